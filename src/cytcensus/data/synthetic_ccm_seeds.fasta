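>ccmB_seed_syn family=B synthetic CcmB seed
MHLPDSFTYNSDNAAIFKGATFGFNLRETHWDVFEMFLKAPTNYPGNDETKKGVQIRNVY
ENVSALMFMQHKVVLPTKTTILRGTRRKYYNYGPHSIQHQAPPHPLPMSPMQQVSMTAIV
FLIMWVGVQPNKLTFFGNIETVELDDSYNWGIWFILKYHHSNPMLRFSNDWEWGFDWRNF
QVHYLTLVVRGYSVSMGDWFAGYNGENRLEARPDGPVMGMMADQMLGTAYVLSNVHVTPI
ESAHSQYQYDWFRPLEASIAGVTERMQYLVKANWNWNPPMTIDFKDRGDDTGMHMAIRIY
>ccmC_seed_syn family=C synthetic CcmC seed
MGLRAMDNAFGIKLNWKTGTWMERIEMTSKDIIHNSDGKTFALTYQSDFWLPQVLYNVQK
SRSDMYPWLQLVATENPSMMHTQQNQLYAMSAVMGPHYKEPQENLINTVSFGEKEPLIGT
PSPGHDHKIRIFMSNRPFTGKIMLSPKLHGPDKDTHYRGKGFGLVQDMLVNDNHEHHQSR
HFNELFQIKFNSGPVGIEKGHPHGWFRYSFISEYWNQMANTVLFMQNVDSEPHENGGWVS
LLFKNIDYIQRMVIVDTSWWEKMLDVVSVQVQNGPFISLDILAPAHKAWYGHYAIRRKYE
>ccmE_seed_syn family=E synthetic CcmE seed
MRDTEWGDGEYKKQSKWIRYEDGMLEGVDTMSTDHVFIGMSSHLFNTGWRIVTHIFPQMT
FPWVPMNWDQSKSKDTISNKRLFDIFSHVITHEPDWKKAHTNVEPAFMKNHPARRIGPWM
QIYETFWGQKFEGPRIFRNQDTHMQVQSRTQRFDEYSNGEGIRNNRMHQDDNKRIMSAEV
LHVLTKQSFQKDNSTFQVMPTPVFLAHNMKAPGPIDNYHQWKKGPWDETTFQQFAHYQLW
RAFTHMWTSTPKPSHAEIARLATYEEYTTNDMREVQPQRWTFAHTHLGMLWWLGWHAHEM
>ccmF_seed_syn family=F synthetic CcmF seed
MNNKKYLIYDMVKFQKIQQIELVRYWYKLYTFANVFYKFQSWPVKHTLPKNLINQQLQHM
GVLTAPIMEEHKLNIKIAAPQHIRFMKEVTDGYWDVVSVRMKDQLDVAWGRGIPRMHGKK
KMDVNTANMDWLHPQSYYYLGYSARMHHQWDTIYYQKIKGSMRNHTHMDYMFHLIGRDQE
QDIWRQNNWSFRDEMNYQHFSAWHYNKVWWKGSWKAFSQTTDMSYVWWEMTFRQWAQRHI
RVVHQTIDSWENKVHWPQIIWGMTNMTPGWYQYYRETPLSWAPEPYRYPDYTMFNYLDQM
>ccmH_seed_syn family=H synthetic CcmH seed
MAGLKQFQMPKLAGIQAYQTAAIAPWEPEWNEFNTYDVGQYTVSHAHWQYYAVIEMKIGA
HQIPWWNLKRALFAKWPFFWMFPGSNPWSAERIWITNAYYITPLSVKIPVFNQAVIESRG
TGYETDRYDLPPHAEGEIVTEPISQYRPINDWQASMFKLNHFYGWSMAIFAIGRMENQPM
IYHQPLKKFWEKQQGMANEQSAPLNSVSRTKTPENRVGHRVTHDQETFFSIRLLHNMVTP
PVPKKWHNEMIETETQSHFPQDDVVDDFVQYFLHNPMHYNDWKLLRMNINHLQYPNPHMP
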