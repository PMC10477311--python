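species,size_class,bites_per_min,bite_area_mm2
Scarus synthetica,10-20,28.0,45.0
Scarus synthetica,20-30,22.0,110.0
Scarus synthetica,30-40,16.0,240.0
Scarus modelus,10-20,30.0,40.0
Scarus modelus,20-30,24.0,100.0
Scarus modelus,30-40,17.0,220.0
Chlorurus fictus,10-20,20.0,60.0
Chlorurus fictus,20-30,15.0,150.0
Chlorurus fictus,30-40,11.0,320.0
Chlorurus exemplaris,20-30,14.0,160.0
Chlorurus exemplaris,30-40,10.0,340.0
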