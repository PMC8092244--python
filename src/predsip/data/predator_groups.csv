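group,token,rank,mode
Bdellovibrionales,bdellovibrionales,order,obligate
Bdellovibrionales,bdellovibrionaceae,family,obligate
Vampirovibrionales,vampirovibrionales,order,obligate
Vampirovibrionales,vampirovibrionaceae,family,obligate
Myxococcales,myxococcales,order,facultative
Myxococcales,myxococcia,class,facultative
Cytophagales,cytophagales,order,facultative
Cytophagales,cytophagia,class,facultative
Lysobacter,lysobacter,genus,facultative
Streptomycetales,streptomycetales,order,facultative
Streptomycetales,streptomycetaceae,family,facultative
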