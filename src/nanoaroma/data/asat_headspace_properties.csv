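name,formula,molar_mass_g_mol,vapor_pressure_pa,odor_threshold_mg_m3,density_kg_m3,families,retention_index
α-Pinene,C10H16,136.23,513,0.240,860,woody(pine),
Camphene,C10H16,136.23,450,,839,woody(camphor),
β-Pinene,C10H16,136.23,390,0.180,873,woody(pine)|oriental,
Limonene,C10H16,136.23,264,0.619,854,citrus,
Z-β-Ocimene,C10H14,134.22,208,0.010,810,floral|herbal,
α-Copaene,C15H24,204.35,5,,939,woody|oriental,
β-Caryophyllene,C15H24,204.35,4,1.500,907,woody|oriental,
α-Humulene,C15H24,204.35,1.1,,889,woody,
β-Selinene,C15H24,204.35,2.3,,914,herbal,
δ-Cadinene,C15H24,204.35,0.9,,910,herbal|woody,
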