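>decoy_recj_syn family=RecJ synthetic RecJ-like exemplar backbone
MTMRWQMPPGNPYWGIPMTIDPMKWNKKNIRVAKRDPLWSWDKQSQSIMAVFVKEDEMGK
DPGERDKQIIAINVQINTLAFSIDSRRWQGPMPMNFVSFQMDCFDCHNLPLMNEEILSPQ
VSYDQPTVGFFYEDSRFKIYDYNQMKVVRTETVVGTNPMAWYDNMFPYVFSVDPCKLCHG
AVTNQVWVETDAMAWIVIIMQRYKELAIFIWWTPKSTVEEDYYIKITTWLNGIFPEKRRI
DNWPSEEFPRWELPALIIKKQLEQMNLWYKENEPWWPFDCDFCHTNGRMNTEFIVSVFYI
ASKNLTNQQKEFFADGLVMRVFNNNMMFMGTESIKLKEGEAIMYDPALYQSQGRSFGNRK
IVWIEMRIVSTLRYEWYSPAKWFTIWSWIYRWNAIETKLIV
>decoy_trx_syn family=thioredoxin synthetic thioredoxin-like exemplar backbone
MKFIFVLLLVIFFLLLVLFFLIFFVLIILVKKELQGFYKAWARANAKYPPAYLAKAGREI
ANTPIISPFVSGDNSWQEYRQLNVRWSTNFEVKYTDQGWRDQEKVGDWWNYMNIVTKWRA
YPQFEWNFMVSMNFQWERKVVSMITFWYWSINIKWWDVRQKYGVMVAEVTGCITCHMFNY
QYLMMKNETKASMGPGGKTDENQNFWSGEWDVREVVLGYPNQNTWDEYEDND
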