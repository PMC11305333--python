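# Synthetic reconstruction of the PL (LOG-family) loss-of-function allele survey across
# prickleless Solanum taxa. The four mapping alleles from the cultivated eggplants, the 12
# additional survey alleles, and the two species pairs sharing identical (not necessarily
# ancestral) alleles follow the published narrative; descriptor position keys and the survey
# taxa marked "taxon_*" are schematic placeholders, so per-row attributions are synthetic
# while the allele arithmetic (18 observations, 16 distinct alleles) is not.
species	gene	effect_class	position_key	source
S. melongena	PL	splice_donor	intron6+1G>A	mapping
S. melongena	PL	large_exonic_deletion	exon6:del474	mapping
S. aethiopicum	PL	frameshift	cds812:del2	mapping
S. macrocarpon	PL	splice_acceptor	intron4-1G>T	mapping
S. donianum	PL	splice_acceptor	intron4-1G>T	survey
S. lanzae	PL	splice_donor	intron2+2T>C	survey
S. stramoniifolium	PL	splice_donor	intron2+2T>C	survey
taxon_01	PL	frameshift	cds205:ins1	survey
taxon_02	PL	stop_gained	cds377C>T	survey
taxon_03	PL	splice_donor	intron1+1G>C	survey
taxon_04	PL	splice_acceptor	intron5-2A>G	survey
taxon_05	PL	frameshift	cds1048:del4	survey
taxon_06	PL	stop_gained	cds92G>A	survey
taxon_07	PL	large_exonic_deletion	exon3:del212	survey
taxon_08	PL	splice_donor	intron3+1G>T	survey
taxon_09	PL	frameshift	cds640:ins2	survey
taxon_10	PL	start_lost	cds2T>G	survey
taxon_11	PL	stop_gained	cds530C>A	survey
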