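(Cycas,(Dioon,(Bowenia,((Macrozamia,(Lepidozamia,Encephalartos)),(Ceratozamia,(Stangeria,(Microcycas,Zamia)))))));
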