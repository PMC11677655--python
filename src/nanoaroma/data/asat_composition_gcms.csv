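compound,area_percent,sd
α-Pinene,39.17,0.67
Camphene,1.81,0.07
β-Pinene,1.05,0.16
p-Cymene,0.39,0.07
Limonene,2.73,0.12
Eucalyptol,0.23,0.01
Z-β-Ocimene,1.76,1.54
E-β-Ocimene,0.15,0.01
γ-Terpinene,0.24,0.01
Terpinolene,0.51,0.11
Exo-fenchol,0.32,0.18
Terpinen-4-ol,0.66,2.20
α-Terpineol,0.37,0.20
α-Copaene,4.09,0.10
Isocaryophyllene,0.23,0.03
β-Caryophyllene,18.71,3.00
β-Gurjunene,0.78,0.38
α-Guaiene,0.26,0.27
α-Humulene,4.79,2.08
Alloaromandrene,0.60,0.46
γ-Muurolene,1.47,0.35
β-Selinene,3.01,0.05
α-Muurolene,1.07,0.10
γ-Cadinene,1.40,0.11
δ-Cadinene,4.05,2.82
trans-Cadina-1.4-diene,0.33,0.20
α-Cadinene,0.29,0.29
α-Calacorene,0.78,0.44
Caryophyllenyl alcohol,1.06,0.40
epi-α-Cadinol,0.61,0.22
α-Cadinol,0.26,0.13
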