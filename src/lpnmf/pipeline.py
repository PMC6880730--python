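"""Dataset assembly: features, similarity networks, and the per-training-
matrix artifacts (profile completion, profile KSNS, fusion) that must be
rebuilt from a masked interaction matrix inside every cross-validation
fold to avoid information leakage.

A dataset carries five lncRNA similarity sources (d2*, KSNS over
expression / PseKNC / PCPseDNC, and KSNS over the completed interaction
profile) and four protein sources (GO semantic, KSNS over APseAAC /
CTriad, and KSNS over the completed profile). Only the profile networks
depend on the interaction matrix; the rest are static per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix, featurize_lncrnas, featurize_proteins
from .model import Hyperparams, ProjectedGraphNMF, ProjectedGraphNMFResults
from .similarity import (
    d2star_similarity,
    fuse_similarities,
    ksns,
    protein_semantic_similarity,
    wknnp_complete,
)
from .simulate import FixtureBundle


@dataclass
class LPIDataset:
    """Everything needed to fit and evaluate on one dataset: ids, the
    interaction matrix, normalized feature views, and the static (A-
    independent) similarity networks on both sides."""

    lncrna_ids: list[str]
    protein_ids: list[str]
    A: np.ndarray
    lnc_views: list[FeatureMatrix]
    prot_views: list[FeatureMatrix]
    static_sims_lnc: list[np.ndarray]
    static_sims_prot: list[np.ndarray]
    ksns_params: dict = field(default_factory=dict)

    @classmethod
    def from_bundle(
        cls,
        bundle: FixtureBundle,
        d2star_k: int = 6,
        ksns_params: dict | None = None,
    ) -> "LPIDataset":
        ksns_params = ksns_params or {}
        lnc_views = featurize_lncrnas(
            bundle.lncrna_seqs, expression=bundle.expression.values
        )
        prot_views = featurize_proteins(bundle.protein_seqs)
        static_lnc = [d2star_similarity(bundle.lncrna_seqs, k=d2star_k).S]
        static_lnc += [ksns(v.values, **ksns_params) for v in lnc_views]
        static_prot = [
            protein_semantic_similarity(
                bundle.annotations, bundle.ontology, bundle.protein_seqs.ids
            ).S
        ]
        static_prot += [ksns(v.values, **ksns_params) for v in prot_views]
        return cls(
            lncrna_ids=list(bundle.lncrna_seqs.ids),
            protein_ids=list(bundle.protein_seqs.ids),
            A=bundle.interactions.A.copy(),
            lnc_views=lnc_views,
            prot_views=prot_views,
            static_sims_lnc=static_lnc,
            static_sims_prot=static_prot,
            ksns_params=ksns_params,
        )


@dataclass
class FoldArtifacts:
    """Interaction-derived quantities rebuilt from one training matrix."""

    A_bar: np.ndarray
    SL_fused: np.ndarray
    SP_fused: np.ndarray


def build_fold_artifacts(
    dataset: LPIDataset,
    A_train: np.ndarray,
    wknnp_decay: float = 0.8,
    restart_prob: float = 0.5,
) -> FoldArtifacts:
    """From a (possibly masked) training matrix: complete it with WKNNP
    using kernel neighborhood similarity of the raw interaction profiles
    as the neighbor metric (profiles is what the completion is named
    after, and it is the only metric guaranteed to reflect the network
    being completed), compute profile KSNS on the completed rows/columns,
    and fuse the static networks with the profile network on each side."""
    prof_sl = ksns(A_train, **dataset.ksns_params)
    prof_sp = ksns(A_train.T, **dataset.ksns_params)
    A_bar = wknnp_complete(A_train, prof_sl, prof_sp, decay=wknnp_decay)
    prof_l = ksns(A_bar, **dataset.ksns_params)
    prof_p = ksns(A_bar.T, **dataset.ksns_params)
    SL = fuse_similarities(
        dataset.static_sims_lnc + [prof_l], restart_prob=restart_prob
    )
    SP = fuse_similarities(
        dataset.static_sims_prot + [prof_p], restart_prob=restart_prob
    )
    return FoldArtifacts(A_bar=A_bar, SL_fused=SL, SP_fused=SP)


def fit_on_training_matrix(
    dataset: LPIDataset,
    A_train: np.ndarray,
    hp: Hyperparams | None = None,
    seed: int | None = None,
) -> tuple[ProjectedGraphNMFResults, np.ndarray]:
    """Rebuild all A-derived artifacts from A_train, fit the model, and
    return the results plus the completed score matrix Y_bar."""
    art = build_fold_artifacts(dataset, A_train)
    model = ProjectedGraphNMF(
        A_train,
        dataset.lnc_views,
        dataset.prot_views,
        art.SL_fused,
        art.SP_fused,
        A_bar=art.A_bar,
        hyperparams=hp,
        lncrna_ids=dataset.lncrna_ids,
        protein_ids=dataset.protein_ids,
    )
    res = model.fit(seed=seed)
    return res, res.predict()
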