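>cytc_mono_syn synthetic monoheme cytochrome c exemplar
MRKILIIIIVVLVLIANAQFMTNVENYWREATQMEDNDDDTVQEIDFSIWFEAGWVIGNA
TIVSTDSGAADRIMRLMWTGPTATFLNGGKNIVYPGNNQDPVWVNAPVAAQVIQNFLYTE
KSWMVFGRNWVCTPCHDSIFPTRRRMVRQLPGPNGMWNNLWQVIIETLEAQVDRQNWW
>cytc_di_syn synthetic diheme cytochrome c exemplar
MKKIIVLVLIVILLAEAKYERTMFAWGLLIDFCWICHEVDSQAWLPWVLPWYDNKKGYVD
VVFGVSISPRGDSQSWDKLMIQLKDYDSREMGAGWKPLFIVWTVMSKIRVVVWIEIEPTM
YRLRDMAQTYPLIYPAAIGFTYRCRMCHKGEMEIDFWAPYQSEAKNFFWTIDSADPTLIK
FQLGLVGSKKETDEANTKPMTNLWDYSYWMISDQPTN
>cytc_multi_syn synthetic multiheme cytochrome c exemplar
MSNTIRAGDDKTVRLSNDTMKPPSDICDLCHLVAVFMKNVKIVELLMDAKMLFADLNMLT
WVAWFMKCLDCHQLADQVGFDLYENVPGTGTGPSRVWELYGPQDPVNIYWSAGVWSALPQ
KSNATQRNVWIPDNEFPRDSLAAVWEMKVPAFCDECHFNWIFPRQARNKMRQSEYGMFRW
TAIDEGGSTSTCEPCHDMLQYRSMSNMWIPEWRTPPAVWYVYWLGRNMNNVLVEGTITSS
KWNWWQMNKPRPGMNDYFYLNCGPCHINMIRMMMYWQKDIISIQDYLIARVFRSEDGDEG
I
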