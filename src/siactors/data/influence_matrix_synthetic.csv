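source,target,topic,level
NL&EU,Farmers,FoA1_3,mandatory
Province,Farmers,FoA1_3,high
Retail,Farmers,FoA1_3,high
Labels,Farmers,FoA1_3,low
Consumers,Farmers,FoA1_3,low
Network,Farmers,FoA1_3,low
Farmer organizations,Farmers,FoA1_3,low
NL&EU,Province,FoA1_3,high
Province,Farmer organizations,FoA1_3,low
Farmers,Network,FoA1_3,low
NL&EU,Farmers,FoA2,mandatory
Retail,Farmers,FoA2,high
Labels,Farmers,FoA2,high
Network,Farmers,FoA2,high
Farmer organizations,Farmers,FoA2,high
Consumers,Retail,FoA2,low
NL&EU,Retail,FoA2,low
Farmers,Network,FoA2,low
Consumers,Farmers,FoA4,high
Network,Farmers,FoA4,high
Retail,Farmers,FoA4,low
Province,Farmers,FoA4,low
Labels,Farmers,FoA4,low
Farmer organizations,Farmers,FoA4,low
Farmers,Network,FoA4,high
Farmers,Consumers,FoA4,high
Farmers,Retail,FoA4,low
Farmers,Farmer organizations,FoA4,low
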