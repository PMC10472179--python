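# Synthetic-cohort scenario for diisurv.ScenarioConfig.from_yaml.
# Every key is optional; omitted keys keep the package defaults shown here.

n_subjects: 6000          # cohort size before exclusions (>= 100)
prop_women: 0.54          # fraction of women
n_parameters: 28          # DII food parameters (1..28, survey-measurable set)

# intake model ------------------------------------------------------------
intake_rho: 0.3           # exchangeable Gaussian-copula correlation
sex_intake_factor: 1.08   # men's intakes exceed women's by this ratio^2
mean_range: [5.0, 300.0]  # drawn per-day reference means (non-macronutrients)
sd_frac_range: [0.2, 0.5] # reference SD as a fraction of the mean
effect_range: [-0.7, 0.7] # inflammatory effect weights, within [-1, 1]
energy_noise_sd: 60.0     # kcal of non-macronutrient energy noise

# hazard model ------------------------------------------------------------
beta_dii: 0.12            # true log hazard ratio per DII unit
# beta_dii_rural: 0.2     # uncomment for an effect-modification scenario
weibull_shape: 1.2
# weibull_scale: 60.0     # years; omit to calibrate to the event target
target_event_fraction: 0.075
event_fraction_band: [0.06, 0.09]
dropout_rate: 0.04        # per year, independent exponential loss

# survey schedule ---------------------------------------------------------
wave_years: [1997, 2000, 2004, 2006, 2009, 2011, 2015]
wave_month_day: [9, 1]
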