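"""Small bundled reference tables."""

from importlib import resources

from .io import read_target_db

#: miRNAs whose expression independently separates IBC from non-IBC after
#: covariate adjustment: six upregulated in IBC, seven downregulated.
IBC_MIRNAS_UP = ("miR-335", "miR-337-5p", "miR-451", "miR-486-3p", "miR-520a-5p", "miR-548d-5p")
IBC_MIRNAS_DOWN = ("miR-15a", "miR-24", "miR-29a", "miR-30b", "miR-320", "miR-342-5p", "miR-342-3p")
IBC_MIRNAS = IBC_MIRNAS_UP + IBC_MIRNAS_DOWN


def direct_target_genes() -> dict[str, set[str]]:
    """Published direct (concordant) target gene lists for the four miRNAs
    whose correlation-defined targets were enriched for sequence-predicted
    targets (miR-29a, miR-30b, miR-342-3p, miR-520a-5p)."""
    path = resources.files("mirna_integrate.data") / "table5_direct_targets.tsv"
    with resources.as_file(path) as p:
        return read_target_db(p)
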