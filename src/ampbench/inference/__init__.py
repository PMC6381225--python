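"""Six de novo amplicon sequence inference strategies behind one interface.

Two similarity-radius OTU methods (plain greedy clustering, and greedy
clustering with inline bimera rejection), three ASV denoisers (abundance-
skew, per-distance subtraction, and divisive partitioning with a learned
error model), and an entropy-decomposition method. Each consumes a
:class:`~ampbench.preprocess.DereplicatedSet` and returns a
:class:`FeatureTable`.
"""

from __future__ import annotations

from typing import Literal

from ..preprocess import DereplicatedSet
from ._table import Feature, FeatureTable, build_table
from .chimera import is_bimera, remove_chimeras
from .dada import DadaParams, DadaResult, denoise_dada, denoise_dada_per_sample
from .deblur import DEFAULT_ERROR_PROFILE, DeblurParams, denoise_deblur
from .mapping import map_reads_to_features
from .med import (
    MedParams,
    decompose_med,
    fixed_threshold,
    max_cluster_entropy,
    med_clusters,
    shannon_column_entropy,
)
from .otu import OtuParams, cluster_greedy_otu, cluster_uparse
from .unoise import UnoiseParams, denoise_unoise, unoise_beta

METHODS = ("uclust", "uparse", "unoise", "deblur", "dada", "med")

#: where chimera removal sits for each method: "inline" during clustering,
#: "post" after inference, or "none" when the zero-profile subtraction
#: model leaves nothing to test
CHIMERA_PLACEMENT = {
    "uclust": "pre-or-post",
    "uparse": "inline",
    "unoise": "post",
    "deblur": "post",
    "dada": "post",
    "med": "post",
}


def run_method(
    method: str,
    derep: DereplicatedSet | dict[str, DereplicatedSet],
    *,
    otu_params: OtuParams | None = None,
    unoise_params: UnoiseParams | None = None,
    deblur_params: DeblurParams | None = None,
    dada_params: DadaParams | None = None,
    med_params: MedParams | None = None,
    total_reads: int | None = None,
    chimera_removal: bool = True,
) -> FeatureTable:
    """Dispatch one inference method with its native chimera handling.

    ``derep`` is a single pooled set for the data-set-level methods, or a
    per-sample dict for the divisive partitioner (which always processes
    samples independently).
    """
    if method == "dada":
        if isinstance(derep, DereplicatedSet):
            derep = {"s1": derep}
        table = denoise_dada_per_sample(derep, dada_params).table
    elif method == "uparse":
        if not isinstance(derep, DereplicatedSet):
            raise TypeError("uparse consumes one pooled DereplicatedSet")
        # chimera rejection is inline during clustering for this method
        table, _ = cluster_uparse(derep, otu_params)
        return table
    else:
        if not isinstance(derep, DereplicatedSet):
            raise TypeError(f"{method} consumes one pooled DereplicatedSet")
        if method == "uclust":
            table = cluster_greedy_otu(derep, otu_params)
        elif method == "unoise":
            table = denoise_unoise(derep, unoise_params)
        elif method == "deblur":
            table = denoise_deblur(derep, deblur_params)
        elif method == "med":
            table = decompose_med(derep, med_params, total_reads)
        else:
            raise ValueError(f"unknown method {method!r}")
    if chimera_removal:
        table, _ = remove_chimeras(table)
    return table
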