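name,half_life_days,mean_beta_energy_keV,max_beta_energy_keV,mean_range_soft_tissue_mm
Lu-177,6.65,133.3,498.3,0.2
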