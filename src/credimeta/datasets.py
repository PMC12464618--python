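"""Packaged example datasets.

Two small TSVs compiled from published meta-analyses of antiepileptic-
drug (AED) resistance pharmacogenetics (2007-2025): the significant
pooled genetic comparisons (one row per meta-analysis x variant x
contrast x subgroup), and the AMSTAR-2 item responses for the 32
systematic meta-analyses appraised.
"""

from __future__ import annotations

from importlib import resources

from .amstar2 import AmstarRecord, read_amstar_tsv
from .pipeline import ComparisonRecord, read_comparisons

__all__ = ["load_aed_comparisons", "load_aed_amstar2",
           "aed_comparisons_path", "aed_amstar2_path"]


def _data_path(name: str):
    return resources.files("credimeta.data") / name


def aed_comparisons_path():
    """Filesystem path of the packaged AED-resistance comparisons TSV."""
    return _data_path("aed_comparisons.tsv")


def aed_amstar2_path():
    """Filesystem path of the packaged AMSTAR-2 item-response TSV."""
    return _data_path("aed_amstar2.tsv")


def load_aed_comparisons(**kwargs) -> list[ComparisonRecord]:
    """The 23 significant pooled comparisons of 7 SNPs in 4 genes."""
    return read_comparisons(aed_comparisons_path(), **kwargs)


def load_aed_amstar2() -> list[AmstarRecord]:
    """AMSTAR-2 item responses of the 32 appraised meta-analyses."""
    return read_amstar_tsv(aed_amstar2_path())
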