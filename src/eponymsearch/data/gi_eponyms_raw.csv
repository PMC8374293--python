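names,term
,Escherichia coli
Crohn's,Disease
Kaposi's,Sarcoma
Chagas',Disease
Behcet’s,Disease
Barrett,Esophagus
Hirschsprung's,Disease
Meckel,Diverticulum
Vater,Ampulla
Oddi,Sphincter
Zollinger and Ellison,Syndrome
Peutz-Jeghers,Syndrome
Whipple's,Disease
Zenker's,Diverticulum
Boerhaave,Syndrome
Caroli,Disease
Menetrier's,Disease
Wirsung,Duct
Klatskin,Tumor
Lieberkuhn,Crypts
Mallory-Weiss,Tear
Santorini,Duct
Schatzki,Ring
"Rokitansky, Aschoff",Sinuses
Rigler,Sign
Carman,Meniscus Sign
Heister,Spiral Valves
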