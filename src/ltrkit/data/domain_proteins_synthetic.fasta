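>GAG_copia_synthetic
LLTFSEANAAFEVSGSILYYVCTTAAELALQSFLERRINLDKPLLRLIAAHPIQLSKHGTSRLYAGDGGCADLLMIAPTLFNVGCEFVNFISLIAPWKFKDESFWHCLKIDFGNADVGNARVSFTMYNNTHGRTTMQRLSTTIRDEGMKTSCLAGPPGFE
>GAG_gypsy_synthetic
RKTLNFKYLARITKLRATHIKASTIDPLLEVIRPSTNEGAQQTEIMMDYPASVFIMAKSNVGEPMLFDNYIVEAAKGGNRVHILPERVFSKEEHMIGRYLKGLGRERYQFICPIFEMSCCYVCANDWIKDMGQNRYCVHNAKIVIQRESATIKVYLPLYH
>PR_copia_synthetic
EVWDHILWENIGQCNSSIKATRVRTPADSVFIEAPHNKNAVLKVGMISMQHVKNGERKDGVVLTNADMSTILKIGGVTDITAFAVAEFQDEPLNSSCLIYAKGLGLPNKA
>PR_gypsy_synthetic
DSHQTVPGNESFLCVRVQQERPEANCVLIARTSGFTPQYWATDLIGSFIELSEIVFYVNQDLDPNECASHGQIPKLFAGIGNYIALLGPDKFAAYNKRLAICNWQTTVGR
>INT_copia_synthetic
TLETAGKTSFTKKPFHDFPVYTPRTKLFVVSRRDAKDGYEVVVSHGAEQFLSIKWVFSLDKLIYRVNLQYCGLKDVAQLRTSFLERLAVPPSIVVHGYCDGEEINAAIKAITDLPLECEPALYFTSSLLNRSTGVFRKRQKRNLVTPKPLFKLPNTIKKMTAAFLSFSYSLQTRYVDGKPRDQEHFRMLWPAQAHYDGIRYTSITLEGFQCIFFGELEPQSLPEPSDLQKQSNVCLSQCALAKSADFRWIMKDKELLTIETSTREDSISRTITQWLRYDA
>INT_gypsy_synthetic
EQTLEFLKEMTEVARQMLLQASLPVPVYMLKQAMTYDIPASQQVKVTPVTWRVSGNTQTGRGVSLYALGSDAYGGIYAFHFNHPFTNGTTVQKHILALEEGDALLGFNIDNRGCNVKVVRYDICIWDGHEQAAFKPLPKAPGPSSVYCKTSYSELKPTPLAFAEPSSKTASIVDLQSLSLLEMKERPLDTRRLYEVIVPDVFDVSRRYARGDGDKTAMLGFHEDLIMITGQEAIGPRRDTDLYKEVSLALRKAKKYQINVFKIQIEVPQLAPEPDGGHIA
>RT_copia_synthetic
TMAGADADFVTEGADVMGDMTDMTSEASDPVTECWGFNIFLSGADARVHADVAQRRVLVLRKRLIAQIPILLILVDCVPSLGEPESIRDMVTPIASCYRIKRGQVNSYEPRVAKQLKGADAEVRYERKTQSDNYIVVNKFQAGADIRKDPAGTSEAQEPENKGLENSATVYIEGKKGMFMAINRSDMSVKMLYGPWVKAYNKQSPGSVCAELRRAQELTRAHSVTIDVRYCSSTELRYSITFGAIPVVLAIQWGNALFAM
>RT_gypsy_synthetic
AFGDSPLSVKAHITSEMGENSFLGNETVVLLRGEEVPDGFFKPGDGSSAKVNIGVTFDNEYELPPEDQVGEDKTVIMGENFVAAEILTVLNGKLEEYGCRAGISSEGVSMNPVDESSDVEPLEGLEGVLDQFIGSEILYERLVPHPSECTQPKTRCPPQPKILTTGDLVEPNATPLVFVPGIVVLSVTELLLISMGRSIANARIVVMSRDDGCGLDQKEAVGTAERLAYPVSLIYGGGWGTEPPRRQEMFLIVQSLEQDG
>RH_copia_synthetic
QFKLWDHMYRPGIKIMFTLIEADMLQDMAIDRDRSLIPKGLDPPGLVEKGDGGLSQSPLLGFDDEDDRRLEVDTLPEAFVGTSAMYFNSTELALDFYLATSRYYAAILPQAFTLAFTKRPCSQWYCTRFVPALNYCCRKK
>RH_gypsy_synthetic
AVHGLEILITGPITATRPGTMPIYGYLVVAKQERGEWWCETKLILHLPKLKAKVFGSPTRFVAWEHLEKDLKVEIRMFAVWVDSTSVRVPFQSEKEKVLLVGEIEKHRVHMGERMWSEAAFDEVRAKKQGEAISEDEHSQ
>CHD_gypsy_synthetic
YHGHAGYQDDRRNITMTRGPVKYEYCQASDANLVVVPQRANTAKFALTNMGPLTDLIIEE
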