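"""Curated reference panels used throughout the analyses.

``DP_GENES`` is the 167-member human developmental transcription-factor
panel (the DLX, FOX, HOX, IRX, LHX, NKX, PAX, POU and SOX families) whose
repeat content, interactomes and functional associations the pipeline
profiles.  ``SPECIES`` is the 55-species eukaryotic reference-proteome panel
(yeast to primates) used for the cross-taxon parameter analyses, as
``(binomial, short_label)`` pairs; ``TAXON_OF_SPECIES`` maps each short
label to its higher-order taxon.
"""

from __future__ import annotations

#: Gene symbols of the 167 human developmental transcription factors.
DP_GENES: tuple[str, ...] = (
    'DLX1', 'DLX2', 'DLX3', 'DLX4', 'DLX5', 'DLX6',
    'FOXA1', 'FOXA2', 'FOXA3', 'FOXB1', 'FOXB2', 'FOXC1',
    'FOXC2', 'FOXD1', 'FOXD2', 'FOXD3', 'FOXD4', 'FOXE1',
    'FOXE3', 'FOXF1', 'FOXF2', 'FOXG1', 'FOXH1', 'FOXI1',
    'FOXI2', 'FOXI3', 'FOXJ1', 'FOXJ2', 'FOXJ3', 'FOXK1',
    'FOXK2', 'FOXL1', 'FOXL2', 'FOXM1', 'FOXN1', 'FOXN2',
    'FOXN3', 'FOXN4', 'FOXO1', 'FOXO3', 'FOXO4', 'FOXO6',
    'FOXP1', 'FOXP2', 'FOXP3', 'FOXP4', 'FOXQ1', 'FOXR1',
    'FOXR2', 'FOXS1', 'FOXD4L1', 'FOXD4L3', 'FOXD4L4', 'FOXD4L5',
    'FOXD4L6', 'HOXA1', 'HOXA2', 'HOXA3', 'HOXA4', 'HOXA5',
    'HOXA6', 'HOXA7', 'HOXA9', 'HOXA10', 'HOXA11', 'HOXA13',
    'HOXB1', 'HOXB2', 'HOXB3', 'HOXB4', 'HOXB5', 'HOXB6',
    'HOXB7', 'HOXB8', 'HOXB9', 'HOXB13', 'HOXC4', 'HOXC5',
    'HOXC6', 'HOXC8', 'HOXC9', 'HOXC10', 'HOXC11', 'HOXC12',
    'HOXC13', 'HOXD1', 'HOXD3', 'HOXD4', 'HOXD8', 'HOXD9',
    'HOXD10', 'HOXD11', 'HOXD12', 'HOXD13', 'IRX1', 'IRX2',
    'IRX3', 'IRX4', 'IRX5', 'IRX6', 'LHX1', 'LHX2',
    'LHX3', 'LHX4', 'LHX5', 'LHX6', 'LHX8', 'LHX9',
    'NKX1-1', 'NKX1-2', 'NKX2-1', 'NKX2-2', 'NKX2-3', 'NKX2-4',
    'NKX2-5', 'NKX2-6', 'NKX2-8', 'NKX3-1', 'NKX3-2', 'NKX6-1',
    'NKX6-2', 'NKX6-3', 'PAX1', 'PAX2', 'PAX3', 'PAX4',
    'PAX5', 'PAX6', 'PAX7', 'PAX8', 'PAX9', 'POU1F1',
    'POU2F1', 'POU2F2', 'POU2F3', 'POU3F1', 'POU3F2', 'POU3F3',
    'POU3F4', 'POU4F1', 'POU4F2', 'POU4F3', 'POU5F1', 'POU5F1B',
    'POU5F2', 'POU6F1', 'POU6F2', 'SOX1', 'SOX2', 'SOX3',
    'SOX4', 'SOX5', 'SOX6', 'SOX7', 'SOX8', 'SOX9',
    'SOX10', 'SOX11', 'SOX12', 'SOX13', 'SOX14', 'SOX15',
    'SOX17', 'SOX18', 'SOX21', 'SOX30', 'SRY',

)

#: The 55-species reference-proteome panel: (binomial, short label).
SPECIES: tuple[tuple[str, str], ...] = (
    ('Homo sapiens', 'Hom sap'),
    ('Pan troglodytes', 'Pan tro'),
    ('Pongo abelii', 'Pon abe'),
    ('Callithrix jacchus', 'Cal jac'),
    ('Otolemur garnetti', 'Oto gar'),
    ('Mus musculus', 'Mus mus'),
    ('Rattus norvegicus', 'Rat nor'),
    ('Heterocephalus glaber', 'Het gla'),
    ('Ailuropoda melanoleuca', 'Ail mel'),
    ('Felis catus', 'Fel cat'),
    ('Bos taurus', 'Bos tau'),
    ('Ovis aries', 'Ovi ari'),
    ('Sus scrofa', 'Sus scr'),
    ('Monodelphis domestica', 'Mon dom'),
    ('Sarcophilus harrisii', 'Sar har'),
    ('Ficedula albicollis', 'Fic alb'),
    ('Taeniopygia guttata', 'Tae gut'),
    ('Gallus gallus', 'Gal gal'),
    ('Meleagris gallopavo', 'Mel gal'),
    ('Anas platyrhynchos', 'Ana pla'),
    ('Anolis carolinensis', 'Ano car'),
    ('Ophiophagus hannah', 'Oph han'),
    ('Astyanax mexicanus', 'Ast mex'),
    ('Danio rerio', 'Dan rer'),
    ('Oryzias latipes', 'Ory lat'),
    ('Xiphophorus maculatus', 'Xip mac'),
    ('Oreochromis niloticus', 'Ore nil'),
    ('Gasterosteus aculeatus', 'Gas acu'),
    ('Takifugu rubripes', 'Tak rub'),
    ('Tetraodon nigroviridis', 'Tet nig'),
    ('Lepisosteus oculatus', 'Lep ocu'),
    ('Apis mellifera', 'Api mel'),
    ('Camponotus floridanus', 'Cam flo'),
    ('Acromyrmex echinatior', 'Acr ech'),
    ('Atta cephalotes', 'Att cep'),
    ('Solenopsis invicta', 'Sol inv'),
    ('Anopheles gambiae', 'Ano gam'),
    ('Anopheles darlingi', 'Ano dar'),
    ('Aedes aegypti', 'Aed aeg'),
    ('Drosophila pseudoobscura', 'Dro pse'),
    ('Drosophila persimilis', 'Dro per'),
    ('Drosophila mojavensis', 'Dro moj'),
    ('Drosophila virilis', 'Dro vir'),
    ('Drosophila grimshawi', 'Dro gri'),
    ('Drosophila melanogaster', 'Dro mel'),
    ('Drosophila sechellia', 'Dro sec'),
    ('Drosophila simulans', 'Dro sim'),
    ('Caenorhabditis remanei', 'Cae rem'),
    ('Caenorhabditis brenneri', 'Cae bre'),
    ('Caenorhabditis briggsae', 'Cae bri'),
    ('Caenorhabditis elegans', 'Cae ele'),
    ('Caenorhabditis japonica', 'Cae jap'),
    ('Komagataella pastoris', 'Kom pas'),
    ('Saccharomyces cerevisiae', 'Sac cer'),
    ('Schizosaccharomyces pombe', 'Sch pom'),
)

#: Higher-order taxon of each species (short label -> taxon code):
#: pri primates, rod rodents, lau Laurasiatheria, mar marsupials,
#: sau Sauropsida, fis fishes, ins insects, nem nematodes, yea yeasts.
_TAXON_BLOCKS: dict[str, tuple[str, ...]] = {
    "pri": ("Hom sap", "Pan tro", "Pon abe", "Cal jac", "Oto gar"),
    "rod": ("Mus mus", "Rat nor", "Het gla"),
    "lau": ("Ail mel", "Fel cat", "Bos tau", "Ovi ari", "Sus scr"),
    "mar": ("Mon dom", "Sar har"),
    "sau": ("Fic alb", "Tae gut", "Gal gal", "Mel gal", "Ana pla",
            "Ano car", "Oph han"),
    "fis": ("Ast mex", "Dan rer", "Ory lat", "Xip mac", "Ore nil",
            "Gas acu", "Tak rub", "Tet nig", "Lep ocu"),
    "ins": ("Api mel", "Cam flo", "Acr ech", "Att cep", "Sol inv",
            "Ano gam", "Ano dar", "Aed aeg", "Dro pse", "Dro per",
            "Dro moj", "Dro vir", "Dro gri", "Dro mel", "Dro sec",
            "Dro sim"),
    "nem": ("Cae rem", "Cae bre", "Cae bri", "Cae ele", "Cae jap"),
    "yea": ("Kom pas", "Sac cer", "Sch pom"),
}

TAXON_OF_SPECIES: dict[str, str] = {
    label: taxon for taxon, members in _TAXON_BLOCKS.items() for label in members
}
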