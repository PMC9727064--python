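# 27-drug Liver-Chip benchmark panel: IQ MPS list membership via matched structural
# pairs, Garside DILI severity rank (1 = severe clinical DILI ... 5 = no DILI), and
# the hepatocyte donors each drug was tested in. Total-plasma C_max and unbound
# fractions were not published per drug and are left blank (supply them to enable
# mass-unit conversions and protein-binding-corrected scoring).
drug,cmax_total_ng_ml,fu_plasma,fu_media,garside_rank,matched_pair,donors
Ambrisentan,,,,5,Sitaxsentan,d1;d2;d3
Asunaprevir,,,,2,,d1
Benoxaprofen,,,,1,,d1;d2
Beta-Estradiol,,,,3,,d1
Buspirone,,,,4,Nefazodone,d1
Chlorpheniramine,,,,3,,d1
Clozapine,,,,2,Olanzapine,d1;d2;d3
Diclofenac,,,,2,,d1
Entacapone,,,,4,Tolcapone,d1
Fialuridine,,,,1,FIRU,d1;d2
FIRU,,,,5,Fialuridine,d1;d2
Labetalol,,,,1,,d1;d2
Levofloxacin,,,,2,Trovafloxacin,d1;d2;d3
Lomitapide,,,,3,,d1
Nefazodone,,,,1,Buspirone,d1
Olanzapine,,,,5,Clozapine,d1;d2;d3
Pioglitazone,,,,3,Troglitazone,d1;d2
Simvastatin,,,,2,,d1;d2
Sitaxsentan,,,,1,Ambrisentan,d1;d2;d3
Stavudine,,,,1,,d1;d2
Tacrine,,,,2,,d1;d2
Telithromycin,,,,1,,d1
Tolcapone,,,,1,Entacapone,d1;d2
Troglitazone,,,,1,Pioglitazone,d1;d2
Trovafloxacin,,,,1,Levofloxacin,d1;d2;d3
Ximelagatran,,,,1,,d1;d2
Zileuton,,,,2,,d1;d2
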