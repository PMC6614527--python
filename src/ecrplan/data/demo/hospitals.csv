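id,name,lat,lon,ecr_capable
H1,Hospital 1,-33.82826723403647,150.83026682543704,True
H2,Hospital 2,-34.016322270942254,150.85797480414482,True
H3,Hospital 3,-33.69436009239718,150.99016499461743,True
H4,Hospital 4,-34.00308809856046,151.11449435622558,True
H5,Hospital 5,-33.78711672562307,151.18445078973602,True
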