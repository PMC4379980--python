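"""Summary statistics: per-superfamily tables, flank-context tabulation,
age histograms, age-vs-redundancy pairing, and library-coverage arithmetic.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

log = logging.getLogger("ltrkit")

FLANK_CLASSES = ("Gene", "Transposon", "Unclassified")


def genome_equivalents(n_clones: int, mean_insert: float, genome_size: float) -> float:
    """Library coverage in genome equivalents, truncated to one decimal.

    Truncation (not rounding) is the reporting convention adopted here:
    it is the only convention consistent with the published figure for
    the olive BAC library (44,928 x 112 kb / 1.49 Gb = 3.377 -> 3.3).
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_clones < 0 or mean_insert < 0:
        raise ValueError("clone count and insert size must be non-negative")
    coverage = n_clones * mean_insert / genome_size
    return math.floor(coverage * 10) / 10


def _mean_se(values: pd.Series) -> tuple[float, float]:
    n = len(values)
    if n == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    if n == 1:
        return mean, 0.0  # degenerate group: SE reported as 0
    return mean, float(values.std(ddof=1) / math.sqrt(n))


def superfamily_table(elements: pd.DataFrame) -> pd.DataFrame:
    """Per-superfamily n and mean +/- SE of length, LTR lengths, rpk, age.

    ``elements`` needs columns: superfamily, length, ltr5_len, ltr3_len,
    and optionally reads_per_kb and age_MY.
    """
    metrics = [c for c in ("length", "ltr5_len", "ltr3_len", "reads_per_kb", "age_MY")
               if c in elements.columns]
    rows = []
    for sf in ("Copia", "Gypsy", "Unknown"):
        grp = elements[elements["superfamily"] == sf]
        row: dict = {"superfamily": sf, "n": len(grp)}
        for m in metrics:
            mean, se = _mean_se(grp[m]) if len(grp) else (float("nan"), float("nan"))
            row[f"{m}_mean"] = round(mean, 2) if not math.isnan(mean) else mean
            row[f"{m}_se"] = round(se, 2) if not math.isnan(se) else se
        rows.append(row)
    return pd.DataFrame(rows)


def flank_context_table(flank_labels: list[tuple[str, str]]) -> pd.DataFrame:
    """Tabulate upstream/downstream flank classes with exact percentages.

    Input is one (upstream, downstream) label pair per element over the
    classes Gene/Transposon/Unclassified.  Rows with zero counts are
    omitted; percentages are exact divisions reported to 2 decimals.
    """
    for up, down in flank_labels:
        if up not in FLANK_CLASSES or down not in FLANK_CLASSES:
            raise ValueError(f"unknown flank class in ({up!r}, {down!r})")
    total = len(flank_labels)
    counts: dict[tuple[str, str], int] = {}
    for pair in flank_labels:
        counts[pair] = counts.get(pair, 0) + 1
    rows = [
        {
            "upstream": up,
            "downstream": down,
            "count": c,
            "percentage": round(100.0 * c / total, 2),
        }
        for (up, down), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


def flank_aggregates(table: pd.DataFrame) -> dict[str, float]:
    """Derived aggregates: near-gene and transposon-adjacent counts/percentages."""
    total = int(table["count"].sum())

    def agg(pred) -> int:
        return int(table[table.apply(pred, axis=1)]["count"].sum())

    near_gene = agg(lambda r: "Gene" in (r["upstream"], r["downstream"]))
    near_te = agg(lambda r: "Transposon" in (r["upstream"], r["downstream"]))
    both_te = agg(lambda r: r["upstream"] == "Transposon" and r["downstream"] == "Transposon")
    return {
        "total": total,
        "near_gene": near_gene,
        "near_gene_pct": round(100.0 * near_gene / total, 2),
        "transposon_adjacent": near_te,
        "transposon_adjacent_pct": round(100.0 * near_te / total, 2),
        "both_sides_transposon": both_te,
        "both_sides_transposon_pct": round(100.0 * both_te / total, 2),
    }


def age_histogram(ages_my: list[float], superfamilies: list[str] | None = None,
                  bin_width: float = 1.0) -> pd.DataFrame:
    """Counts of elements per half-open age bin [k, k+bin_width), per group."""
    if any(a < 0 for a in ages_my):
        raise ValueError("ages must be non-negative")
    if not ages_my:
        return pd.DataFrame(columns=["bin_start", "group", "count"])
    groups = superfamilies if superfamilies is not None else ["all"] * len(ages_my)
    df = pd.DataFrame({"age": ages_my, "group": groups})
    df["bin_start"] = (df["age"] // bin_width) * bin_width
    out = (
        df.groupby(["bin_start", "group"]).size().reset_index(name="count")
        .sort_values(["bin_start", "group"]).reset_index(drop=True)
    )
    return out


def age_redundancy_table(ages: pd.DataFrame, rpk: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Join per-element ages and reads/kb; return the table and Spearman rho.

    ``ages`` needs columns element_id, age_MY; ``rpk`` needs element_id,
    reads_per_kb.  Mismatched id sets are an error.  With constant input
    on either side the correlation is reported as 0 with a tie note.
    """
    if set(ages["element_id"]) != set(rpk["element_id"]):
        raise ValueError("age and redundancy tables cover different elements")
    merged = ages.merge(rpk, on="element_id").sort_values("element_id").reset_index(drop=True)
    if merged["age_MY"].nunique() <= 1 or merged["reads_per_kb"].nunique() <= 1:
        log.warning("constant ranks; Spearman correlation undefined, reported as 0")
        return merged, 0.0
    rho, _ = spearmanr(merged["age_MY"], merged["reads_per_kb"])
    return merged, float(rho)
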