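group_a,group_b,geographic_m,linearized_fst
lower_outflow,upper_outflow,4655,0.02104
lower_outflow,bunaveela,4747,0.01484
lower_outflow,lower_inflow,4936,0.0154
lower_outflow,middle_inflow,5556,0.01656
lower_outflow,upper_inflow,5645,0.02835
upper_outflow,bunaveela,92,0.00173
upper_outflow,lower_inflow,281,0.003
upper_outflow,middle_inflow,901,0.00443
upper_outflow,upper_inflow,990,0.01016
bunaveela,lower_inflow,102,0.00042
bunaveela,middle_inflow,722,0.00179
bunaveela,upper_inflow,811,0.00918
lower_inflow,middle_inflow,620,-0.00166
lower_inflow,upper_inflow,709,0.00551
middle_inflow,upper_inflow,89,0.00404
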