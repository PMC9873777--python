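# Meko: early-maturing, short-stature improved variety.
name = "Meko"

# Cardinal temperatures, emergence to anthesis (deg C)
t_base_veg = 6.0
t_opt_veg = 27.0
t_max_veg = 42.0

# Cardinal temperatures, anthesis to maturity (plateau above t_opt)
t_base_gf = 5.7
t_opt_gf = 23.5

# Accumulated thermal-time targets (deg C day)
tt_emerg_to_pi = 347.0
tt_flag_to_anthesis = 207.0
tt_anthesis_to_maturity = 819.0
tt_sow_to_emerg = 40.0
tt_anthesis_to_startgf = 100.0

# Canopy development
lar = 63.0   # leaf appearance rate, deg C day per leaf
lir = 31.5   # leaf initiation rate, deg C day per leaf
tln = 15.0   # total leaf number (phenology)
tln_canopy = 15   # leaf number used for the leaf-size profile
x0_slope = 0.83
x0_intercept = 0.0
y0_slope = 36.9
y0_intercept = -95.2

# Crop growth
partition_k = 0.0073           # leaf-stem partitioning factor
grain_number_factor = 0.00083  # g per grain
rue = 1.25                     # g biomass per MJ intercepted radiation
extinction_k = 0.4
max_kernel_wt = 0.028          # g per grain
stem_transloc_frac = 0.2
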