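ligand_id	affinity	ligand_efficiency
ZINC200458361	-12.7	0.41
ZINC144529139	-12.6	0.39
ZINC73196087	-12.6	0.45
ZINC72318117	-12.5	0.44
ZINC72318118	-12.5	0.41
ZINC73163075	-12.5	0.42
ZINC96284612	-12.5	0.41
ZINC150080371	-12.4	0.38
ZINC299865209	-12.4	0.42
ZINC43176957	-12.4	0.43
ZINC73165724	-12.4	0.39
ZINC73196196	-12.4	0.43
ZINC72318119	-12.3	0.41
ZINC150078084	-12.2	0.37
ZINC96284613	-12.2	0.39
ZINC144475075	-12.1	0.4
ZINC40431067	-12.1	0.37
ZINC84759584	-12.1	0.36
ZINC96284618	-12.1	0.37
ZINC144529348	-12.0	0.41
ZINC166085169	-12.0	0.38
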