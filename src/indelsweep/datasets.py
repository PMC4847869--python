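"""Bundled study tables and named demographic models.

Two small TSV fixtures ship with the package: the PCR-based deletion
frequency survey across twelve populations (line counts, latitudes,
allele counts) and the North American pooled-sequencing read counts over
the indel junction. Both are inputs to the clinal and pooled-frequency
analyses and to the worked examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coalescent import DemographicModel

_MODEL_FILES = {
    "constant": None,
    "duchen": "duchen.yaml",
    "werzner": "werzner.yaml",
    "thornton-andolfatto": "thornton_andolfatto.yaml",
}

#: Haplotype partition of the Dutch sample at the focal 49-bp deletion:
#: 12 sequences, 41 segregating sites overall, 18 among the 10 deletion
#: carriers (23 among the 2 non-carriers).
DUTCH_HAPLOTYPE_PARTITION = {
    "n": 12,
    "S_total": 41,
    "carriers": 10,
    "carrier_S": 18,
    "non_carrier_S": 23,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("indelsweep._data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def deletion_survey() -> pd.DataFrame:
    """Deletion frequencies from the 12-population PCR survey.

    Columns: population, latitude (signed degrees), n_lines, n_alleles
    (two alleles per isofemale line), del_alleles, frequency (as
    printed), sub_saharan (0/1).
    """
    return _read("table1.tsv")


def poolseq_survey() -> pd.DataFrame:
    """North American pooled-sequencing counts over the indel junction.

    Columns: population, latitude, n_autosomes, informative_reads
    (reads spanning the junction), del_reads (matching the deletion
    allele).
    """
    return _read("table2.tsv")


def demographic_model(name: str) -> DemographicModel:
    """Load a named demographic model shipped with the package.

    ``constant`` plus three out-of-Africa bottleneck slots with
    placeholder parameters (see the YAML files for caveats).
    """
    if name not in _MODEL_FILES:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_MODEL_FILES)}"
        )
    fname = _MODEL_FILES[name]
    if fname is None:
        return DemographicModel.constant()
    path = resources.files("indelsweep._data").joinpath(fname)
    with resources.as_file(path) as p:
        return DemographicModel.from_yaml(p)
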