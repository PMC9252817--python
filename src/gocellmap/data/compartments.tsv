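name	go_id	views
Cytoplasm	GO:0005737	standard
Cytoskeleton	GO:0005856	standard
Endoplasmic reticulum	GO:0005783	standard
Endosome	GO:0005768	standard
Extracellular region	GO:0005576	standard
Golgi apparatus	GO:0005794	standard;endosomal
Intracellular vesicle	GO:0097708	standard;endosomal
Lysosome	GO:0005764	standard;endosomal
Mitochondrion	GO:0005739	standard
Nucleus	GO:0005634	standard
Peroxisome	GO:0005777	standard
Plasma membrane	GO:0005886	standard;endosomal
Ribosome	GO:0005840	standard
Vacuole	GO:0005773	standard
Early endosome	GO:0005769	endosomal
Late endosome	GO:0005770	endosomal
Recycling endosome	GO:0055037	endosomal
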