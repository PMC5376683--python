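"""Pseudo-temporal differentiation model over discrete fibroblast subgroups.

Each subgroup (differentiation state) gets a per-gene pseudo-temporal score —
the product of detection frequency and mean expression level — which treats
switch-like regulation (frequency changes at constant level) and transitional
regulation (level changes at constant frequency) on an equal footing. Marker
rules then name the states:

* stem-like               highest pluripotency score (normal side)
* naive                   lowest activation-marker score among normal states
* primed                  the remaining normal state
* secretory myofibroblast highest soluble-factor score among activated states
* ECM myofibroblast       highest COL1A1/FN1 score among the rest
* proto-myofibroblast     the remaining activated state

and the canonical pseudo-timeline orders them stem-like -> naive -> primed ->
proto -> ECM -> secretory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .panel import GenePanel

logger = logging.getLogger("scfib")

STATE_LABELS = (
    "stem_like",
    "naive",
    "primed",
    "proto_myofibroblast",
    "ecm_myofibroblast",
    "secretory_myofibroblast",
)

NORMAL_LABELS = ("stem_like", "naive", "primed")
ACTIVATED_LABELS = ("proto_myofibroblast", "ecm_myofibroblast", "secretory_myofibroblast")

#: default marker rule set (gene lists per criterion); editable via config
DEFAULT_MARKER_RULES = {
    "pluripotency_group": "pluripotency",
    "activation_markers": ["ACTA2", "COL1A1", "TNC", "FN1", "FAP", "MMP2"],
    "soluble_markers": ["CXCL12", "PDGFA", "VEGFA", "HGF"],
    "ecm_markers": ["COL1A1", "FN1"],
}


@dataclass
class PseudoTemporalProfile:
    """Gene x state score matrix, score = frequency x non-negative level."""

    score: pd.DataFrame  # genes x states
    states: list
    level_convention: str = "mean log2 RQ over detected cells, floored at 0"

    def __post_init__(self) -> None:
        if not np.isfinite(self.score.to_numpy(dtype=float)).all():
            raise ValueError("profile scores must be finite")


@dataclass
class StateModel:
    """Ordered differentiation states with labels and their marker scores."""

    states: list  # state ids in current order
    labels: dict  # state id -> label
    marker_scores: pd.DataFrame  # states x rule criteria
    profile: PseudoTemporalProfile

    def label_order(self) -> list:
        return [self.labels[s] for s in self.states]

    def state_for(self, label: str):
        for s, lab in self.labels.items():
            if lab == label:
                return s
        raise KeyError(f"no state labelled {label!r}")


def pseudotemporal_profile(
    summary: pd.DataFrame, states: list, level_scale: str = "log2"
) -> PseudoTemporalProfile:
    """score(gene, state) = frequency x level, with level floored at 0.

    ``summary`` is the (gene, group) table from ``summarize_groups``; every
    listed state must be present. Zero frequency forces a zero score even when
    the level is undefined. ``level_scale="linear"`` uses 2**level instead of
    the floored log2 level (alternative convention, ordering-equivalent).
    """
    present = summary.index.get_level_values("group").unique()
    missing = [s for s in states if s not in present]
    if missing:
        raise ValueError(f"states absent from summary: {missing}")
    genes = summary.index.get_level_values("gene").unique()
    score = pd.DataFrame(0.0, index=genes, columns=states)
    for state in states:
        sub = summary.xs(state, level="group").reindex(genes)
        freq = sub["frequency"].to_numpy(dtype=float)
        level = sub["level"].to_numpy(dtype=float)
        if level_scale == "log2":
            lvl = np.maximum(np.nan_to_num(level, nan=0.0), 0.0)
        elif level_scale == "linear":
            lvl = np.nan_to_num(2.0**level, nan=0.0)
        else:
            raise ValueError(f"unknown level_scale {level_scale!r}")
        score[state] = np.where(freq == 0, 0.0, freq * lvl)
    convention = (
        "mean log2 RQ over detected cells, floored at 0"
        if level_scale == "log2"
        else "linear RQ (2**mean log2) over detected cells"
    )
    return PseudoTemporalProfile(score=score, states=list(states), level_convention=convention)


def _rule_genes(rule, panel: GenePanel) -> list:
    if isinstance(rule, str):  # a gene-group name
        genes = panel.genes_in_group(rule)
        if not genes:
            raise ValueError(f"gene group {rule!r} is empty")
        return genes
    return [panel.resolve(g) for g in rule]


def label_states(
    profile: PseudoTemporalProfile,
    panel: GenePanel,
    conditions: dict,
    rules: dict | None = None,
) -> StateModel:
    """Assign the six differentiation-state labels from marker scores.

    ``conditions`` maps each state id to "normal" or "activated" (normal
    states compete for stem-like/naive/primed, activated states for the three
    myofibroblast labels). Ties break toward the lower state id (input order),
    with a logged warning. Missing sides yield the corresponding subset only.
    """
    rules = {**DEFAULT_MARKER_RULES, **(rules or {})}
    score = profile.score
    missing_cond = [s for s in profile.states if s not in conditions]
    if missing_cond:
        raise ValueError(f"no condition given for states: {missing_cond}")

    crit = pd.DataFrame(index=profile.states, dtype=float)
    for name, rule in (
        ("pluripotency", rules["pluripotency_group"]),
        ("activation", rules["activation_markers"]),
        ("soluble", rules["soluble_markers"]),
        ("ecm", rules["ecm_markers"]),
    ):
        genes = _rule_genes(rule, panel)
        absent = [g for g in genes if g not in score.index]
        if absent:
            raise ValueError(f"marker rule {name!r} references genes absent from profile: {absent}")
        crit[name] = score.loc[genes].mean(axis=0)

    normal = [s for s in profile.states if conditions[s] == "normal"]
    activated = [s for s in profile.states if conditions[s] == "activated"]
    labels: dict = {}

    def pick(cands: list, column: str, how: str) -> object:
        sub = crit.loc[cands, column]
        best = sub.max() if how == "max" else sub.min()
        winners = sorted((s for s in cands if sub[s] == best), key=str)
        if len(winners) > 1:
            logger.warning("tie on %s criterion among states %s; lowest id wins", column, winners)
        return winners[0]

    if normal:
        stem = pick(normal, "pluripotency", "max")
        labels[stem] = "stem_like"
        rest = [s for s in normal if s != stem]
        if rest:
            naive = pick(rest, "activation", "min")
            labels[naive] = "naive"
            rest = [s for s in rest if s != naive]
        if len(rest) == 1:
            labels[rest[0]] = "primed"
        elif rest:
            raise ValueError(f"cannot label states uniquely: {len(rest) + 2} normal states")
    if activated:
        secretory = pick(activated, "soluble", "max")
        labels[secretory] = "secretory_myofibroblast"
        rest = [s for s in activated if s != secretory]
        if rest:
            ecm = pick(rest, "ecm", "max")
            labels[ecm] = "ecm_myofibroblast"
            rest = [s for s in rest if s != ecm]
        if len(rest) == 1:
            labels[rest[0]] = "proto_myofibroblast"
        elif rest:
            raise ValueError(f"cannot label states uniquely: {len(rest) + 2} activated states")

    if len(set(labels.values())) != len(labels):
        raise ValueError(f"duplicate labels assigned: {labels}")
    return StateModel(
        states=list(profile.states), labels=labels, marker_scores=crit, profile=profile
    )


def order_states(model: StateModel) -> StateModel:
    """Reorder states onto the canonical pseudo-timeline.

    Works for the full six-state model or any labelled subset (e.g. a
    normal-only run keeps stem-like -> naive -> primed).
    """
    assigned = set(model.labels.values())
    order = [lab for lab in STATE_LABELS if lab in assigned]
    unlabelled = [s for s in model.states if s not in model.labels]
    if unlabelled:
        raise ValueError(f"states without labels cannot be ordered: {unlabelled}")
    new_states = [model.state_for(lab) for lab in order]
    profile = PseudoTemporalProfile(
        score=model.profile.score[new_states],
        states=new_states,
        level_convention=model.profile.level_convention,
    )
    return StateModel(
        states=new_states,
        labels=dict(model.labels),
        marker_scores=model.marker_scores.loc[new_states],
        profile=profile,
    )


def cluster_profiles(
    profile: PseudoTemporalProfile,
    n_clusters: int = 2,
    extreme_range_factor: float = 5.0,
) -> pd.DataFrame:
    """Hierarchically cluster gene rows of the profile (Euclidean, average).

    Returns a per-gene table with the flat cluster at the requested cut and an
    ``extreme`` flag for genes whose score range exceeds
    ``extreme_range_factor`` x the median gene range (the "plot separately"
    convention for genes with extremely pronounced differences).
    """
    score = profile.score
    genes = list(score.index)
    ranges = score.max(axis=1) - score.min(axis=1)
    med = float(np.median(ranges)) if len(ranges) else 0.0
    extreme = ranges > extreme_range_factor * med if med > 0 else pd.Series(False, index=genes)
    if len(genes) == 1:
        clusters = np.array([1])
    else:
        z = linkage(score.to_numpy(dtype=float), method="average", metric="euclidean")
        clusters = fcluster(z, t=min(n_clusters, len(genes)), criterion="maxclust")
    return pd.DataFrame(
        {"cluster": clusters, "score_range": ranges, "extreme": extreme}, index=genes
    )
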