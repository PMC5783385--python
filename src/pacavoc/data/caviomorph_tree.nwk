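(((Ctenomys_talarum,Spalacopus_cyanus),Octodon_degus),((Cavia_aperea,(Kerodon_rupestris,Hydrochoerus_hydrochaeris)),Dasyprocta_leporina));
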