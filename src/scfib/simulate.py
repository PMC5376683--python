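"""Synthetic single-cell qPCR generator with planted differentiation states.

The generator emulates the study design the analysis assumes: two conditions
(normal vs tumour-activated fibroblasts) whose cells occupy six latent
differentiation states along a planted pseudo-timeline, a 43-gene panel with
per-gene, per-state detection probabilities f and detected-expression means mu
(log2 relative quantities), biological + technical Gaussian noise, a per-cell
global-scale offset (differences in absolute RNA content), switch-like
regulation (f varies, mu near-constant: HGF, CCL5, pluripotency and BCSC-like
genes) versus transitional regulation (mu varies at near-constant f), and a
bimodal activation marker (ACTA2 drawn from a two-component mixture in
activated cells).

Cohort sizes default to the study's: 92 control + 91 experimental CAFs for the
cell-line reference, 77 normal + 75 CAF for the patient cohort. The planted
cluster truth on the reference has five groups — the primed (normal) and
proto-myofibroblast (activated) states are molecularly adjacent and form one
mixed cluster, matching the manual five-subgroup split with a mixed group.

Every draw is reproducible from the seed, and full ground truth (state,
cluster, global offset, mixture component) is returned for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .panel import CqPlate, GenePanel, load_default_panel

STATES = ("state1", "state2", "state3", "state4", "state5", "state6")
STATE_CONDITION = {
    "state1": "normal", "state2": "normal", "state3": "normal",
    "state4": "activated", "state5": "activated", "state6": "activated",
}
#: planted five-group cluster truth: primed + proto form the mixed cluster
CLUSTER_OF_STATE = {
    "state1": "cluster1", "state2": "cluster2", "state3": "cluster3",
    "state4": "cluster3", "state5": "cluster4", "state6": "cluster5",
}

# per gene: (detection probability, detected log2-RQ mean), scalars broadcast
# across the six states stem -> naive -> primed -> proto -> ecm -> secretory
_PROFILES = {
    # epithelial: rare in fibroblasts throughout
    "CDH1": (0.05, 2.0),
    "EPCAM": (0.05, 2.0),
    "KRT18": (0.08, 2.5),
    # activation markers ramp up along the timeline (ACTA2 bimodal when activated);
    # transitional genes keep near-constant high detection so regulation is level-driven
    "ACTA2": ([0.8, 0.75, 0.85, 0.95, 0.95, 0.95], [1.5, 1.5, 2.625, 5.0, 5.0, 5.0]),
    "COL1A1": (0.98, [4.0, 2.5, 7.0, 7.5, 10.5, 5.0]),
    "TNC": ([0.85, 0.8, 0.9, 0.95, 0.95, 0.95], [1.2, 1.5, 5.0, 5.5, 7.5, 5.0]),
    "FN1": (0.98, [4.0, 2.5, 6.5, 7.0, 10.0, 5.0]),
    "FAP": (0.95, [2.0, 2.0, 4.125, 5.375, 6.5, 6.5]),
    "S100A4": (0.95, [4.0, 4.0, 8.0, 6.625, 4.5, 4.5]),  # FSP1 marks the primed state
    "MMP2": (0.95, [4.5, 3.0, 7.5, 7.0, 9.0, 5.5]),
    "LOX": (0.92, [2.0, 2.0, 5.0, 5.5, 8.0, 4.5]),
    "LOXL2": (0.92, [2.0, 2.0, 5.0, 5.5, 7.5, 4.5]),
    # mesenchymal markers ramp down with activation
    "VIM": (0.98, [9.0, 9.0, 8.0, 7.125, 5.5, 5.0]),
    "CD44": (0.98, [8.0, 8.0, 6.5, 5.625, 4.0, 3.5]),
    "CAV1": (0.98, [8.5, 8.5, 7.0, 6.0, 4.0, 3.5]),
    # chemokines / soluble factors peak in the secretory state
    "CXCL12": ([0.8, 0.8, 0.85, 0.9, 0.9, 0.98], [1.5, 1.5, 2.5, 3.875, 5.0, 10.0]),
    "PDGFA": (0.92, [2.0, 2.0, 3.0, 4.0, 4.5, 9.5]),
    "VEGFA": (0.95, [2.5, 2.5, 3.5, 4.5, 5.0, 9.0]),
    "HGF": ([0.5, 0.2, 0.3, 0.525, 0.45, 0.9], [6.0, 5.0, 5.0, 5.0, 5.0, 7.0]),  # switch-like
    "CCL5": ([0.95, 0.15, 0.1, 0.1, 0.1, 0.2], [8.0, 5.0, 5.0, 5.0, 5.0, 5.5]),  # with pluripotency
    "CCL2": (0.9, [3.0, 3.0, 3.5, 4.0, 4.5, 7.5]),
    "IL6": (0.85, [3.0, 3.0, 3.0, 3.5, 4.0, 7.0]),
    "FGF2": (0.9, [3.5, 3.5, 4.0, 4.0, 4.5, 6.0]),
    # transcription factors: mildly diverged
    "SNAI1": (0.9, [3.0, 3.0, 3.5, 4.875, 5.0, 5.0]),
    "SNAI2": (0.92, [4.0, 4.0, 4.0, 4.5, 5.0, 5.0]),
    "TWIST1": (0.9, [3.0, 3.0, 3.5, 4.875, 5.0, 4.5]),
    "ZEB1": (0.9, [3.5, 3.5, 4.0, 4.5, 4.5, 4.5]),
    "HIF1A": (0.95, [5.0, 5.0, 5.0, 5.5, 5.5, 6.0]),
    # proliferation: low in the quiescent stem-like state; p21 the other way
    "CCNA2": ([0.1, 0.9, 0.9, 0.9, 0.75, 0.75], [2.0, 6.0, 6.0, 6.0, 5.0, 5.0]),
    "MKI67": ([0.1, 0.85, 0.85, 0.85, 0.7, 0.7], [2.0, 6.0, 6.0, 6.0, 5.0, 5.0]),
    "CCND1": (0.92, [3.5, 5.0, 5.0, 5.0, 5.0, 5.0]),
    "CDKN1A": (0.95, [9.0, 4.0, 4.0, 4.0, 4.0, 4.0]),
    # BCSC-like: switch-like, enriched on the normal side; ALDH1A3 ramps up instead
    "ALDH1A3": ([0.8, 0.75, 0.85, 0.9, 0.95, 0.95], [1.2, 1.0, 3.0, 4.375, 6.5, 7.5]),
    "ALDH1A1": ([0.95, 0.4, 0.3, 0.25, 0.2, 0.2], 4.5),
    "CD24": ([0.8, 0.35, 0.3, 0.25, 0.2, 0.2], 4.0),
    "PROM1": ([0.7, 0.25, 0.2, 0.15, 0.1, 0.1], 3.5),
    "ITGA6": ([0.85, 0.45, 0.4, 0.35, 0.3, 0.3], 4.5),
    # pluripotency: on only in the stem-like state (switch-like)
    "POU5F1": ([0.95, 0.03, 0.02, 0.02, 0.02, 0.02], 9.0),
    "SOX2": ([0.95, 0.03, 0.02, 0.02, 0.02, 0.02], 8.5),
    "NANOG": ([0.95, 0.03, 0.02, 0.02, 0.02, 0.02], 8.5),
    "KLF4": ([0.95, 0.05, 0.03, 0.03, 0.03, 0.03], 9.0),
    # EMT
    "CDH2": (0.95, [6.0, 6.0, 6.0, 6.5, 6.5, 6.5]),
    # reference gene: high, stable; detection = sort efficiency
    "GAPDH": (0.95, 10.0),
}


def _profile_frames(panel: GenePanel) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = panel.genes
    f = pd.DataFrame(index=genes, columns=list(STATES), dtype=float)
    mu = pd.DataFrame(index=genes, columns=list(STATES), dtype=float)
    for g in genes:
        fg, mg = _PROFILES[g]
        f.loc[g] = np.broadcast_to(np.asarray(fg, dtype=float), (6,))
        mu.loc[g] = np.broadcast_to(np.asarray(mg, dtype=float), (6,))
    return f, mu


@dataclass
class GeneratorConfig:
    """Planted study design: states, per-gene f/mu trajectories and noise.

    sigma_bio (log2 units) and sigma_tech (Cq cycles, one cycle = one log2
    unit) combine in quadrature; global_scale_sd is the SD of the per-cell
    offset added to every detected log2 value. ``bimodal`` overrides the
    per-state mean for one gene in activated cells with a two-component draw.
    ``gapdh_detection`` replaces GAPDH's planted f (set to 1.0 to disable
    GAPDH dropout); ``censor_at_cutoff`` switches non-detect generation from
    true absence to censoring of values beyond the Cq cutoff.
    """

    panel: GenePanel = field(default_factory=load_default_panel)
    states: tuple = STATES
    pseudotime_order: tuple = STATES
    n_cells: dict = field(
        default_factory=lambda: {
            "control": {"state1": 9, "state2": 41, "state3": 42},
            "expCAF": {"state4": 31, "state5": 30, "state6": 30},
        }
    )
    f: pd.DataFrame | None = None
    mu: pd.DataFrame | None = None
    sigma_bio: float = 1.0
    sigma_tech: float = 0.5
    global_scale_sd: float = 0.5
    bimodal: dict = field(
        default_factory=lambda: {
            "gene": "ACTA2", "means": (3.0, 7.0), "weights": (0.5, 0.5)
        }
    )
    gapdh_detection: float = 0.95
    cq_cutoff: float = 28.0
    censor_at_cutoff: bool = False

    def __post_init__(self) -> None:
        if self.f is None or self.mu is None:
            f, mu = _profile_frames(self.panel)
            self.f = self.f if self.f is not None else f
            self.mu = self.mu if self.mu is not None else mu
        if sorted(self.pseudotime_order) != sorted(self.states):
            raise ValueError("pseudotime_order must be a permutation of states")
        fv = self.f.to_numpy(dtype=float)
        if np.any((fv < 0) | (fv > 1)):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if min(self.sigma_bio, self.sigma_tech, self.global_scale_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not np.isclose(sum(self.bimodal["weights"]), 1.0):
            raise ValueError("bimodal component weights must sum to 1")
        if not 0 <= self.gapdh_detection <= 1:
            raise ValueError("gapdh_detection must lie in [0, 1]")

    @property
    def sigma_total(self) -> float:
        return float(np.hypot(self.sigma_bio, self.sigma_tech))

    def with_(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth for every generated cell and gene."""

    cells: pd.DataFrame  # index cell_id: cell_class, condition, state, cluster,
    #                      global_offset, bimodal_component
    f: pd.DataFrame  # planted detection probabilities (gene x state)
    mu: pd.DataFrame  # planted detected-expression means (gene x state)

    def state_labels(self) -> pd.Series:
        return self.cells["state"]

    def cluster_labels(self) -> pd.Series:
        return self.cells["cluster"]


def _draw_cells(
    config: GeneratorConfig,
    rng: np.random.Generator,
    plan: list,  # (cell_id, cell_class, condition, state or (f_row, mu_row, state))
) -> tuple[CqPlate, SyntheticTruth]:
    genes = config.panel.genes
    n = len(plan)
    cq = np.full((n, len(genes)), np.nan)
    meta_rows = []
    bimodal_gene = config.bimodal["gene"]
    bm_means = np.asarray(config.bimodal["means"], dtype=float)
    bm_weights = np.asarray(config.bimodal["weights"], dtype=float)
    gi = {g: j for j, g in enumerate(genes)}

    for i, (cell_id, cell_class, condition, state, f_row, mu_row) in enumerate(plan):
        offset = rng.normal(0.0, config.global_scale_sd) if config.global_scale_sd else 0.0
        component = np.nan
        fvec = f_row.copy()
        if config.gapdh_detection is not None:
            fvec[gi["GAPDH"]] = config.gapdh_detection
        detected = rng.random(len(genes)) < fvec
        means = mu_row.copy()
        if condition == "activated" and bimodal_gene in gi:
            component = int(rng.choice(len(bm_means), p=bm_weights))
            means[gi[bimodal_gene]] = bm_means[component]
            if not detected[gi[bimodal_gene]]:
                component = np.nan
        log2rq = rng.normal(means + offset, config.sigma_total)
        cq_row = config.cq_cutoff - log2rq
        cq_row = np.clip(cq_row, 1e-6, None)  # Cq must stay positive
        if config.censor_at_cutoff:
            detected &= cq_row <= config.cq_cutoff
        cq[i, detected] = cq_row[detected]
        meta_rows.append(
            {
                "cell_id": cell_id,
                "sample_id": cell_class,
                "cell_class": cell_class,
                "condition": condition,
                "state": state,
                "cluster": CLUSTER_OF_STATE.get(state, state),
                "global_offset": offset,
                "bimodal_component": component,
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    plate = CqPlate(
        cq=pd.DataFrame(cq, index=meta.index, columns=genes),
        cells=meta[["sample_id", "cell_class"]],
        panel=config.panel,
    )
    truth = SyntheticTruth(
        cells=meta[
            ["cell_class", "condition", "state", "cluster", "global_offset", "bimodal_component"]
        ],
        f=config.f.copy(),
        mu=config.mu.copy(),
    )
    return plate, truth


def generate_reference(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[CqPlate, SyntheticTruth]:
    """Generate the cell-line reference experiment (92 control + 91 expCAF).

    Cells are laid out per (condition, state) at the configured counts; each
    cell draws a global-scale offset, per-gene Bernoulli detection and normal
    log2 expression around the planted state mean, converted to Cq as
    cutoff - log2RQ. Identical config + seed gives identical plates.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    plan = []
    counter = 0
    for cell_class, per_state in config.n_cells.items():
        condition = "normal" if cell_class in ("control", "NF") else "activated"
        for state, count in per_state.items():
            f_row = config.f[state].to_numpy(dtype=float)
            mu_row = config.mu[state].to_numpy(dtype=float)
            for _ in range(count):
                counter += 1
                plan.append(
                    (f"{cell_class}_{counter:04d}", cell_class, condition, state, f_row, mu_row)
                )
    return _draw_cells(config, rng, plan)


def generate_patient_cohort(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    n_nf: int = 77,
    n_caf: int = 75,
    nf_state_probs: dict | None = None,
) -> tuple[CqPlate, SyntheticTruth]:
    """Generate the patient experiment (77 normal + 75 CAF cells).

    Normal fibroblasts draw their state from a stem/naive/primed mixture;
    patient CAFs sit on a uniform interpolation between the primed and
    proto-myofibroblast archetypes (their truth state is the nearer endpoint).
    The per-cell global-scale SD defaults to twice the reference value to
    exercise per-cell autoscaling.
    """
    base = config if config is not None else GeneratorConfig().with_(global_scale_sd=1.0)
    rng = np.random.default_rng(seed)
    nf_state_probs = nf_state_probs or {"state1": 0.10, "state2": 0.60, "state3": 0.30}
    states = list(nf_state_probs)
    probs = np.asarray([nf_state_probs[s] for s in states], dtype=float)
    probs = probs / probs.sum()

    plan = []
    draws = rng.choice(len(states), size=n_nf, p=probs)
    for i, si in enumerate(draws, start=1):
        state = states[si]
        plan.append(
            (
                f"NF_{i:04d}", "NF", "normal", state,
                base.f[state].to_numpy(dtype=float),
                base.mu[state].to_numpy(dtype=float),
            )
        )
    f3, f4 = base.f["state3"].to_numpy(float), base.f["state4"].to_numpy(float)
    m3, m4 = base.mu["state3"].to_numpy(float), base.mu["state4"].to_numpy(float)
    alphas = rng.uniform(0.0, 1.0, size=n_caf)
    for i, a in enumerate(alphas, start=1):
        state = "state3" if a < 0.5 else "state4"
        plan.append(
            (
                f"CAF_{i:04d}", "CAF", "activated", state,
                (1 - a) * f3 + a * f4,
                (1 - a) * m3 + a * m4,
            )
        )
    return _draw_cells(base, rng, plan)


def truth_metrics(truth_labels: pd.Series, predicted: pd.Series) -> dict:
    """Score a clustering or classification against planted truth.

    Returns the adjusted Rand index (label-vocabulary agnostic), plain
    accuracy (meaningful when both sides share a vocabulary) and the
    confusion table. Indices must align.
    """
    predicted = predicted if isinstance(predicted, pd.Series) else predicted.labels
    if set(truth_labels.index) != set(predicted.index):
        raise ValueError("cell ids of truth and prediction do not match")
    predicted = predicted.reindex(truth_labels.index)
    ari = float(adjusted_rand_score(truth_labels.to_numpy(), predicted.to_numpy()))
    accuracy = float((truth_labels.astype(str) == predicted.astype(str)).mean())
    confusion = pd.crosstab(truth_labels, predicted)
    return {"ari": ari, "accuracy": accuracy, "confusion": confusion}
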