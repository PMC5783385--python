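species,group_size_mid,repertoire_size
Ctenomys_talarum,1,4
Dasyprocta_leporina,2,8
Cavia_aperea,2,8
Octodon_degus,4,7
Kerodon_rupestris,4.5,10
Spalacopus_cyanus,8.5,11
Hydrochoerus_hydrochaeris,9.5,6
Cuniculus_paca,,6
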