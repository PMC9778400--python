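"""Ligand-based virtual-screening funnel.

Similarity enrichment against seed compounds, canonical-SMILES
deduplication, QED/molecular-weight drug-likeness and element filters,
then activity prediction and ranking with a published or fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit.Chem import Descriptors
from rdkit.Chem.QED import qed as _rdkit_qed

from .compound_io import (
    Compound,
    CompoundSet,
    ConfigurationError,
    canonicalize,
    element_set,
    ic50_from_pic50,
)
from .descriptors_2d import compute_descriptor_vector
from .fingerprints_clustering import circular_fingerprint, tanimoto
from .qsar_model import MLRModel, predict

__all__ = [
    "ScreeningConfig",
    "Candidate",
    "enrich_by_similarity",
    "deduplicate",
    "qed",
    "molecular_weight",
    "druglike_filter",
    "element_filter",
    "rank_candidates",
    "run_funnel",
]


@dataclass(frozen=True)
class ScreeningConfig:
    similarity_threshold: float = 0.8
    fingerprint_radius: int = 2
    fingerprint_nbits: int = 2048
    qed_min: float = 0.5
    mw_max: float = 650.0
    element_whitelist: Optional[frozenset[str]] = None  # None: union over seeds
    activity_threshold_rule: str = "above_mean_seed"  # above_max_seed | explicit
    activity_threshold_value: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity threshold must be in (0, 1]")
        if not 0.0 <= self.qed_min <= 1.0:
            raise ValueError("qed_min must be in [0, 1]")
        if self.mw_max <= 0:
            raise ValueError("mw_max must be positive")
        if self.activity_threshold_rule not in (
            "above_mean_seed",
            "above_max_seed",
            "explicit",
        ):
            raise ValueError(f"unknown rule {self.activity_threshold_rule!r}")
        if self.activity_threshold_rule == "explicit" and self.activity_threshold_value is None:
            raise ValueError("explicit rule requires activity_threshold_value")


@dataclass(frozen=True)
class Candidate:
    compound: Compound
    best_seed_id: str
    best_similarity: float
    qed: float
    mw: float
    pic50_pre: float
    passes_threshold: bool

    @property
    def ic50_pre_micromolar(self) -> float:
        return 10.0 ** (6.0 - self.pic50_pre)


def _seed_fps(seeds: CompoundSet, config: ScreeningConfig):
    return [
        (
            s.id,
            circular_fingerprint(
                s, radius=config.fingerprint_radius, nbits=config.fingerprint_nbits
            ),
        )
        for s in seeds
    ]


def enrich_by_similarity(
    library: CompoundSet, seeds: CompoundSet, config: ScreeningConfig = ScreeningConfig()
) -> tuple[CompoundSet, dict[str, tuple[str, float]]]:
    """Keep library members with max circular-fingerprint Tanimoto to any
    seed strictly above the threshold.

    Returns the retained set and, per retained id, (best seed id, similarity).
    """
    if len(seeds) == 0:
        raise ConfigurationError("seed set is empty")
    seed_fps = _seed_fps(seeds, config)
    kept: list[Compound] = []
    provenance: dict[str, tuple[str, float]] = {}
    for c in library:
        fp = circular_fingerprint(
            c, radius=config.fingerprint_radius, nbits=config.fingerprint_nbits
        )
        best_id, best_sim = max(
            ((sid, tanimoto(sfp, fp)) for sid, sfp in seed_fps), key=lambda t: t[1]
        )
        if best_sim > config.similarity_threshold:
            kept.append(c)
            provenance[c.id] = (best_id, best_sim)
    return CompoundSet(kept, provenance="similarity-enriched"), provenance


def deduplicate(compounds: CompoundSet) -> CompoundSet:
    """One record per canonical SMILES; first occurrence wins."""
    seen: set[str] = set()
    kept = []
    for c in compounds:
        canon = canonicalize(c.smiles)
        if canon in seen:
            continue
        seen.add(canon)
        kept.append(c)
    return CompoundSet(kept, provenance="deduplicated")


def qed(compound: Compound | str) -> float:
    """Bickerton weighted-desirability drug-likeness, in [0, 1]."""
    mol = compound.mol() if isinstance(compound, Compound) else None
    if mol is None:
        from .compound_io import mol_from_smiles

        mol = mol_from_smiles(compound)
    return float(_rdkit_qed(mol))


def molecular_weight(compound: Compound | str) -> float:
    mol = compound.mol() if isinstance(compound, Compound) else None
    if mol is None:
        from .compound_io import mol_from_smiles

        mol = mol_from_smiles(compound)
    return float(Descriptors.MolWt(mol))


def druglike_filter(
    compounds: CompoundSet, config: ScreeningConfig = ScreeningConfig()
) -> tuple[CompoundSet, dict[str, int]]:
    """Keep compounds with QED >= qed_min and MW <= mw_max."""
    kept = []
    rejections = {"qed": 0, "mw": 0}
    for c in compounds:
        if molecular_weight(c) > config.mw_max:
            rejections["mw"] += 1
        elif qed(c) < config.qed_min:
            rejections["qed"] += 1
        else:
            kept.append(c)
    return CompoundSet(kept, provenance="druglike-filtered"), rejections


def element_filter(
    compounds: CompoundSet, whitelist: frozenset[str] | set[str]
) -> CompoundSet:
    """Keep compounds whose element set is a subset of the whitelist."""
    if not whitelist:
        raise ConfigurationError("element whitelist is empty")
    whitelist = frozenset(whitelist)
    kept = [c for c in compounds if element_set(c) <= whitelist]
    return CompoundSet(kept, provenance="element-filtered")


def _activity_threshold(seeds: CompoundSet, config: ScreeningConfig) -> float:
    if config.activity_threshold_rule == "explicit":
        return float(config.activity_threshold_value)
    seed_pic50 = [s.pic50 for s in seeds if s.pic50 is not None]
    if not seed_pic50:
        raise ConfigurationError("no seed pIC50 values for activity threshold")
    if config.activity_threshold_rule == "above_max_seed":
        return max(seed_pic50)
    return float(np.mean(seed_pic50))


def rank_candidates(
    compounds: CompoundSet,
    model: MLRModel,
    seeds: CompoundSet,
    config: ScreeningConfig = ScreeningConfig(),
    descriptor_source: Callable[[Compound], dict] = compute_descriptor_vector,
    similarity_provenance: Optional[dict[str, tuple[str, float]]] = None,
) -> list[Candidate]:
    """Predict activity for every compound and sort by predicted pIC50.

    Descending by prediction, ties broken by id for a stable order; each
    candidate is flagged against the configured activity-threshold rule.
    """
    import math

    threshold = _activity_threshold(seeds, config)
    failures = []
    rows = []
    for c in compounds:
        descriptors = descriptor_source(c)
        if any(
            isinstance(v, float) and math.isnan(v)
            for k, v in descriptors.items()
            if k in model.coefficients
        ):
            failures.append(c.id)
            continue
        pic50_pre = float(predict(model, descriptors))
        seed_id, sim = (similarity_provenance or {}).get(c.id, ("", float("nan")))
        rows.append(
            Candidate(
                compound=c,
                best_seed_id=seed_id,
                best_similarity=sim,
                qed=qed(c),
                mw=molecular_weight(c),
                pic50_pre=pic50_pre,
                passes_threshold=pic50_pre > threshold,
            )
        )
    if failures:
        raise ValueError(f"missing model descriptors for compounds: {failures}")
    return sorted(rows, key=lambda cand: (-cand.pic50_pre, cand.compound.id))


def run_funnel(
    library: CompoundSet,
    seeds: CompoundSet,
    model: MLRModel,
    config: ScreeningConfig = ScreeningConfig(),
) -> tuple[list[Candidate], dict[str, int]]:
    """The full screening funnel; returns candidates and per-stage counts."""
    counts = {"library": len(library)}
    enriched, provenance = enrich_by_similarity(library, seeds, config)
    counts["enriched"] = len(enriched)
    unique = deduplicate(enriched)
    counts["deduplicated"] = len(unique)
    druglike, _ = druglike_filter(unique, config)
    counts["druglike"] = len(druglike)
    whitelist = config.element_whitelist or frozenset().union(
        *(element_set(s) for s in seeds)
    )
    elemental = element_filter(druglike, whitelist)
    counts["element_filtered"] = len(elemental)
    candidates = rank_candidates(
        elemental, model, seeds, config, similarity_provenance=provenance
    )
    counts["ranked"] = len(candidates)
    counts["passing_threshold"] = sum(c.passes_threshold for c in candidates)
    return candidates, counts


def write_candidates(candidates: Sequence[Candidate], stream) -> None:
    stream.write(
        "id,smiles,best_seed,similarity,qed,mw,pic50_pre,ic50_pre_uM,passes_threshold\n"
    )
    for c in candidates:
        stream.write(
            f"{c.compound.id},{c.compound.smiles},{c.best_seed_id},"
            f"{c.best_similarity:.4f},{c.qed:.4f},{c.mw:.2f},"
            f"{c.pic50_pre:.4f},{c.ic50_pre_micromolar:.3f},{int(c.passes_threshold)}\n"
        )
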