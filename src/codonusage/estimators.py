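"""scikit-learn-style transformers over gene panels.

:class:`RscuVectorizer` turns a panel (list of CodingSequence) into the
genes × 59 RSCU matrix consumed by :class:`~codonusage.multivariate_stats.RscuPCA`.

:class:`CodonUsageProfiler` is the workhorse: ``fit`` builds (or adopts)
the CAI reference-weight table, ``transform`` produces the per-gene
profile table — composition, synonymous GC3, ENc, CAI59/CAI18,
dinucleotide odds ratios, PR2 coordinates and protein indices — that the
force-attribution and correlation analyses consume. Both follow the
estimator contract (get_params/set_params, fitted attributes with a
trailing underscore) and compose with sklearn pipelines.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import codon_metrics, composition, dinucleotide, protein_props
from .codon_metrics import ReferenceWeights, build_reference_weights
from .forces import parity_point
from .sequence_io import CodingSequence

__all__ = ["RscuVectorizer", "CodonUsageProfiler"]


def _check_panel(X) -> list[CodingSequence]:
    panel = list(X)
    if not panel:
        raise ValueError("empty panel")
    for item in panel:
        if not isinstance(item, CodingSequence):
            raise TypeError(
                f"expected CodingSequence, got {type(item).__name__}"
            )
    return panel


class RscuVectorizer(TransformerMixin, BaseEstimator):
    """Panel → genes × 59 RSCU matrix (NaN where a family is absent)."""

    def fit(self, X, y=None):
        _check_panel(X)
        self.n_features_out_ = 59
        return self

    def transform(self, X) -> pd.DataFrame:
        return codon_metrics.rscu_frame(_check_panel(X))


class CodonUsageProfiler(TransformerMixin, BaseEstimator):
    """Per-gene codon-usage and protein-index profile table.

    Parameters
    ----------
    cai_reference
        ``"panel"`` (default): pool the fitted panel's codon counts into
        the CAI reference weights; or a pre-built
        :class:`~codonusage.codon_metrics.ReferenceWeights`.
    include_protein_indices
        Skip the (comparatively expensive) protein indices when False.

    Fitted attribute: ``reference_weights_``.
    """

    def __init__(
        self,
        cai_reference: str | ReferenceWeights = "panel",
        include_protein_indices: bool = True,
    ):
        self.cai_reference = cai_reference
        self.include_protein_indices = include_protein_indices

    def fit(self, X, y=None):
        panel = _check_panel(X)
        if isinstance(self.cai_reference, ReferenceWeights):
            self.reference_weights_ = self.cai_reference
        elif self.cai_reference == "panel":
            self.reference_weights_ = build_reference_weights(panel)
        else:
            raise ValueError(
                "cai_reference must be 'panel' or a ReferenceWeights instance"
            )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "reference_weights_")
        panel = _check_panel(X)
        rows = []
        for cds in panel:
            prof = composition.composition_profile(cds)
            row: dict[str, float] = {"gene_id": cds.gene_id}
            row.update(prof.as_dict())
            row["gc3_synonymous"] = composition.gc3_synonymous(cds)
            row["length_codons"] = cds.codon_count
            enc_val = codon_metrics.enc(cds)
            row["enc"] = np.nan if enc_val.enc is None else enc_val.enc
            try:
                cai_res = codon_metrics.cai(cds, self.reference_weights_)
                row["cai59"] = cai_res.cai59
                row["cai18"] = cai_res.cai18
            except ValueError:
                row["cai59"] = np.nan
                row["cai18"] = np.nan
            for d, v in dinucleotide.dinucleotide_odds(cds).rho.items():
                row[f"rho_{d}"] = v
            pr2 = parity_point(prof)
            row["pr2_x"] = pr2.x
            row["pr2_y"] = pr2.y
            if self.include_protein_indices:
                protein = protein_props.translate(cds)
                row.update(protein_props.protein_indices(protein).as_dict())
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene_id")

    def fit_transform(self, X, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X).transform(X)


def profile_panel(
    panel: Sequence[CodingSequence],
    cai_reference: str | ReferenceWeights = "panel",
    include_protein_indices: bool = True,
) -> pd.DataFrame:
    """Functional wrapper around :class:`CodonUsageProfiler`."""
    return CodonUsageProfiler(
        cai_reference=cai_reference,
        include_protein_indices=include_protein_indices,
    ).fit_transform(panel)
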