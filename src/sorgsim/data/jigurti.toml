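# Jigurti: late-maturing, tall landrace.
name = "Jigurti"

t_base_veg = 6.6
t_opt_veg = 27.0
t_max_veg = 42.0

t_base_gf = 5.7
t_opt_gf = 23.5

tt_emerg_to_pi = 450.0
tt_flag_to_anthesis = 222.0
tt_anthesis_to_maturity = 801.0
tt_sow_to_emerg = 40.0
tt_anthesis_to_startgf = 100.0

lar = 58.0
lir = 29.0
# Phenology leaf number back-solves the 450 deg C day target ((19.5-4)*29);
# the observed plants carried 16-19 leaves, so the leaf-size profile uses 19.
tln = 19.5
tln_canopy = 19
x0_slope = 0.74
x0_intercept = 0.0
y0_slope = 13.2
y0_intercept = 318.0

partition_k = 0.0106
grain_number_factor = 0.0014
rue = 1.65
extinction_k = 0.4
max_kernel_wt = 0.032
stem_transloc_frac = 0.2
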