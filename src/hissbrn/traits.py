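"""Canonical trait ordering shared by the multivariate and path stages."""

#: Fixed order of the five traits entering the among-individual matrix.
TRAIT_ORDER: tuple[str, ...] = (
    "nest_defence",
    "lay_date",
    "clutch_size",
    "fledgling_number",
    "fledgling_mass",
)
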