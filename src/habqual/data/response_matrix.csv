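variable,service,fitness,density,area,published_label
bio1,seed,↓↓↓,↓↓↓,↓↓↓,
bio2,seed,↑↑↑,↑↑↑,↑↑↑,
bio3,seed,↑↑↑,↓↓↓,–,N
bio4,seed,↓↓↓,↑↑↑,–,N
bio5,seed,↓↓↓,↓↓↓,↓↓↓,
bio6,seed,↓↓↓,↓↓↓,↓↓↓,
bio7,seed,–,↑↑↑,↑↑↑,D
bio8,seed,↓↓↓,↓↓↓,↓↓↓,
bio9,seed,↓↓↓,↓↓↓,↓↓↓,
bio10,seed,↓↓↓,↓↓↓,↓↓↓,
bio11,seed,↓↓↓,↓↓↓,↓↓↓,
bio12,seed,↑,↓↓↓,–,N
bio13,seed,↑↑,↓↓↓,–,N
bio14,seed,↑↑↑,↓↓↓,↓,D
bio15,seed,↑↑↑,↑↑↑,↑↑↑,
bio16,seed,↑↑,↓↓↓,–,N
bio17,seed,↑↑↑,↓↓↓,↓,D
bio18,seed,–,↓↓↓,–,F
bio19,seed,↑↑↑,↓↓↓,–,N
sand_pct,seed,↓↓↓,–↑,↓↓,F
clay_pct,seed,↑↑,–,↑,F
silt_pct,seed,↑↑↑,–,↑↑↑,F
bulk_density,seed,↑,↑↑↑,–,
org_carbon,seed,↑↑,↓↓↓,–,N
ph,seed,↓↓↓,↑↑↑,–,N
elevation,seed,↑↑↑,↑↑↑,↑↑↑,
slope,seed,↓↓↓,↓↓↓,↓↓↓,
tri,seed,↓↓↓,↓↓↓,↓↓↓,
bio1,agb,↓↓↓,↓↓↓,↓↓↓,
bio2,agb,–,↑↑↑,↑↑↑,D
bio3,agb,↑↑↑,↓↓↓,↓,D
bio4,agb,↓↓,↑↑↑,–,N
bio5,agb,↓↓↓,↓↓↓,↓↓↓,
bio6,agb,↑↑,↓↓↓,↓↓↓,D
bio7,agb,↓↓↓,↑↑↑,↑↑↑,D
bio8,agb,↓↓↓,↓↓↓,↓↓↓,
bio9,agb,↓,↓↓↓,↓↓↓,
bio10,agb,↓↓↓,↓↓↓,↓↓↓,
bio11,agb,↓↓,↓↓↓,↓↓↓,
bio12,agb,↑↑↑,↓↓↓,↓↓↓,D
bio13,agb,↑↑↑,↓↓↓,↓↓↓,D
bio14,agb,↑↑,↓↓↓,↓↓↓,D
bio15,agb,↓,↑↑↑,↑↑↑,D
bio16,agb,↑↑↑,↓↓↓,↓↓↓,D
bio17,agb,–↑,↓↓↓,↓↓↓,D
bio18,agb,–,↓↓↓,–↓,D
bio19,agb,↑↑,↓↓↓,↓,D
sand_pct,agb,–,–↑,–,F
clay_pct,agb,–,–,–,
silt_pct,agb,–,–,–,
bulk_density,agb,–,↑↑↑,–,F
org_carbon,agb,↑,↓↓↓,–,N
ph,agb,↓↓↓,↑↑↑,–,N
elevation,agb,↑↑↑,↑↑↑,↑↑↑,
slope,agb,↓↓↓,↓↓↓,↓↓↓,
tri,agb,↓↓↓,↓↓↓,↓↓↓,
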