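species,precursor_mz,product_mz,collision_energy,tube_lens,polarity,is_internal_standard
FA 18:3-OOMxP,405.3,333.3,11,57,positive,false
FA 18:2-OOMxP,407.3,335.3,13,57,positive,false
FA 18:1-OOMxP,409.2,207.3,14,57,positive,false
FA 19:1-OOMxP,423.4,221.3,14,62,positive,true
FA 20:5-OOMxP,429.3,357.3,12,64,positive,false
FA 20:4-OOMxP,431.4,359.4,13,64,positive,false
FA 22:6-OOMxP,455.3,383.4,12,53,positive,false
FA 22:1-OOMxP,465.4,263.3,15,65,positive,false
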