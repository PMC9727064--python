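# Published margin-of-safety (MOS)-like values for the 27-drug benchmark panel:
# free assay concentration at the minimum toxic level divided by total plasma C_max
# (uncorrected basis). ">x" = censored bound, no toxicity observed up to the largest
# multiple tested. Empty cell = drug not tested in that donor / model.
drug,mos_donor1,mos_donor2,mos_both,mos_spheroid
Ambrisentan,>3,>10,>10,>127
Asunaprevir,4,,,
Benoxaprofen,0.001,0.3,0.001,>0.7
Beta-Estradiol,>5,,,22500
Buspirone,>15,,,16300
Chlorpheniramine,>200,,,2141
Clozapine,1.8,5,1.8,14.5
Diclofenac,1.8,,,6.1
Entacapone,>6,,,46.5
Fialuridine,0.1,2.8,0.1,12.3
FIRU,>108,>108,>108,
Labetalol,26,22,22,0.41
Levofloxacin,>11.3,>33.7,>33.7,>20
Lomitapide,0,,,
Nefazodone,1.4,,,6.8
Olanzapine,>20,>2,>20,
Pioglitazone,2.8,>2.8,2.8,>5.3
Simvastatin,17,45,17,460
Sitaxsentan,0.04,1.6,0.04,8.7
Stavudine,247,107,107,>144
Tacrine,>12,>12,>12,696
Telithromycin,6,,,
Tolcapone,0.004,0.05,0.004,0.3
Troglitazone,0.03,0.1,0.03,2.3
Trovafloxacin,20,19,19,>24.9
Ximelagatran,30,300,30,335
Zileuton,>7,15,15,>7.7
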