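"""Synthetic tri-modal cohorts with planted subtypes, gradients and survival.

The generator emulates the statistical shapes of a multi-omic tumor cohort
at desk scale: log-scale gene expression with subtype signature modules,
logit-normal methylation beta values bounded in [0, 1], and microbiome
abundances simulated as negative-binomial counts and then passed through
the same counts -> CPM -> log2(CPM + 1) chain the analysis assumes.

Nine default groups echo the structure of the real cohort the pipeline was
designed around:

* ``viral`` — marked in microbiome (one strongly elevated genus) and
  expression, the analogue of a virus-driven subtype;
* ``hypomethyl`` — separable ONLY through methylation: a global
  hypomethylation shift on the logit scale, while in expression each of
  its samples carries a private random signature module (heterogeneous,
  no shared direction), so no single-modality expression analysis can
  group it;
* ``emt`` — mesenchymal marker module up, epithelial module down;
* ``a_like``, ``c_like`` — generic expression-signature subtypes;
* ``grad_1`` .. ``grad_4`` — a continuous differentiation arm: each sample
  carries a latent gradient value u in [0, 1] (quartile slices per group);
  the basal marker module declines linearly in u, a methylation probe
  module rises with u (anti-correlated), and one genus tracks u.  The four
  groups also carry small discrete signatures so they are recoverable as
  clusters while the continuum drives the embedding axis.

Survival times are exponential with per-subtype hazards (the steep end of
the gradient arm carries a 3x hazard relative to its start) under uniform
independent censoring calibrated to a target censored fraction.
Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .downstream import BASAL_MARKERS, EPITHELIAL_MARKERS, MESENCHYMAL_MARKERS
from .omics_io import ClinicalTable, OmicsMatrix

logger = logging.getLogger("omicsfuse")

SUBTYPES = [
    "viral", "hypomethyl", "emt", "a_like", "c_like",
    "grad_1", "grad_2", "grad_3", "grad_4",
]

# relative event rates per subtype; grad_4 is 3x grad_1
HAZARD_MULTIPLIERS = {
    "viral": 0.5, "hypomethyl": 0.5, "emt": 0.5, "a_like": 1.0, "c_like": 1.5,
    "grad_1": 1.0, "grad_2": 1.4, "grad_3": 2.0, "grad_4": 3.0,
}


@dataclass
class SimConfig:
    """Generator parameters (defaults are the study conditions).

    Effect sizes are expressed in noise-SD units and converted per
    modality; ``beta_sd`` is the logit-scale methylation noise SD and
    ``hypomethyl_shift`` the global logit shift of the hypomethylated
    group.  ``nb_size`` is the negative-binomial size (inverse
    dispersion) of microbiome counts.
    """

    n_per_group: int = 40
    n_genes: int = 200
    n_probes: int = 500
    n_genera: int = 60
    module_size: int = 15
    probe_module_size: int = 40
    effect_sd_units: float = 2.5
    gradient_amplitude: float = 3.0
    # gradient-arm slices are marked, not walled off: their discrete
    # signatures get this fraction of the full effect so that neighbor
    # graphs stay connected across slice boundaries and the arm remains a
    # traversable continuum, as in a differentiation trajectory
    grad_discreteness: float = 0.6
    beta_sd: float = 0.8
    hypomethyl_shift: float = -1.0
    nb_size: float = 5.0
    censor_frac: float = 0.3
    base_hazard: float = 1.0 / 60.0  # events per month
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group, self.n_genes, self.n_probes, self.n_genera,
               self.module_size, self.probe_module_size) < 1:
            raise ValueError("sizes must be positive")
        if not (0 <= self.censor_frac < 1):
            raise ValueError("censor_frac must lie in [0, 1)")
        if self.beta_sd <= 0 or self.nb_size <= 0 or self.base_hazard <= 0:
            raise ValueError("scales must be positive")
        if not np.isfinite([self.effect_sd_units, self.gradient_amplitude,
                            self.hypomethyl_shift]).all():
            raise ValueError("effect sizes must be finite")


@dataclass
class CohortTruth:
    """Ground-truth channel: labels, latent gradient, hazards."""

    sample_ids: list[str]
    subtype: np.ndarray  # string label per sample
    gradient_u: np.ndarray  # in [0,1] on the gradient arm, NaN elsewhere
    hazard: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.subtype) == len(self.gradient_u) == len(self.hazard) == n):
            raise ValueError("truth arrays must match sample count")
        on_arm = np.char.startswith(self.subtype.astype(str), "grad_")
        if np.isnan(self.gradient_u[on_arm]).any() or (~np.isnan(self.gradient_u[~on_arm])).any():
            raise ValueError("gradient_u must be defined exactly on the gradient arm")

    @property
    def labels_numeric(self) -> np.ndarray:
        order = {s: i + 1 for i, s in enumerate(SUBTYPES)}
        return np.array([order[s] for s in self.subtype])


def _gene_ids(n_genes: int) -> list[str]:
    markers = BASAL_MARKERS + MESENCHYMAL_MARKERS + EPITHELIAL_MARKERS
    if n_genes < len(markers) + 50:
        raise ValueError(f"n_genes must be at least {len(markers) + 50}")
    fillers = [f"GENE{i:04d}" for i in range(n_genes - len(markers))]
    return markers + fillers


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(cfg: SimConfig | None = None):
    """Generate one cohort.

    Returns (expression, methylation, microbiome, clinical, truth) with a
    shared, lexicographically ordered sample axis.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_group * len(SUBTYPES)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    subtype = np.repeat(SUBTYPES, cfg.n_per_group)

    # latent gradient: grad_i occupies the i-th quartile of [0, 1]
    gradient_u = np.full(n, np.nan)
    for i in range(4):
        m = subtype == f"grad_{i + 1}"
        gradient_u[m] = rng.uniform(i / 4, (i + 1) / 4, size=m.sum())

    gene_ids = _gene_ids(cfg.n_genes)
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    marker_count = len(BASAL_MARKERS) + len(MESENCHYMAL_MARKERS) + len(EPITHELIAL_MARKERS)

    # disjoint signature modules drawn from the non-marker genes
    signature_owners = ["viral", "emt", "a_like", "c_like",
                       "grad_1", "grad_2", "grad_3", "grad_4"]
    free = np.arange(marker_count, cfg.n_genes)
    need = cfg.module_size * len(signature_owners) + 30  # +30 gradient module
    if len(free) < need:
        raise ValueError("n_genes too small for the signature modules")
    picked = rng.choice(free, size=need, replace=False)
    modules = {
        owner: picked[i * cfg.module_size : (i + 1) * cfg.module_size]
        for i, owner in enumerate(signature_owners)
    }
    gradient_module = picked[len(signature_owners) * cfg.module_size :]

    # --- expression: per-gene Gaussian on the log scale -------------------
    base_expr = rng.normal(6.0, 2.0, size=cfg.n_genes)
    mean = np.tile(base_expr, (n, 1))
    shift = cfg.effect_sd_units  # noise SD is 1 on the log scale
    for owner, module in modules.items():
        s = shift * cfg.grad_discreteness if owner.startswith("grad_") else shift
        mean[np.ix_(subtype == owner, module)] += s
    emt_m = subtype == "emt"
    for g in MESENCHYMAL_MARKERS:
        mean[emt_m, gene_pos[g]] += shift
    for g in EPITHELIAL_MARKERS:
        mean[emt_m, gene_pos[g]] -= shift
    # hypomethylated tumors span heterogeneous expression states: each
    # sample perturbs its own private random module, so the group shares
    # no expression direction and cannot be grouped from expression alone
    for i in np.flatnonzero(subtype == "hypomethyl"):
        private = rng.choice(np.arange(marker_count, cfg.n_genes),
                             size=cfg.module_size, replace=False)
        mean[i, private] += shift
    # the gradient arm: basal markers and the gradient module decline in u
    eff_u = gradient_u
    arm = ~np.isnan(eff_u)
    grad_cols = np.concatenate([[gene_pos[g] for g in BASAL_MARKERS], gradient_module])
    mean[np.ix_(arm, grad_cols)] += cfg.gradient_amplitude * (1.0 - eff_u[arm])[:, None]
    expression = mean + rng.normal(0.0, 1.0, size=(n, cfg.n_genes))

    # --- methylation: logit-normal betas ----------------------------------
    probe_ids = [f"cg{i:06d}" for i in range(cfg.n_probes)]
    base_meth = rng.normal(0.0, 2.0, size=cfg.n_probes)
    logit = np.tile(base_meth, (n, 1))
    logit[subtype == "hypomethyl", :] += cfg.hypomethyl_shift
    probe_module = rng.choice(cfg.n_probes, size=cfg.probe_module_size, replace=False)
    meth_shift = cfg.effect_sd_units * cfg.beta_sd
    logit[np.ix_(arm, probe_module)] += meth_shift * eff_u[arm][:, None]
    logit += rng.normal(0.0, cfg.beta_sd, size=(n, cfg.n_probes))
    methylation = _sigmoid(logit)

    # --- microbiome: NB counts -> CPM -> log2(CPM + 1) ---------------------
    genus_ids = ["Alphapapillomavirus", "Lactobacillus"] + [
        f"Genus{i:03d}" for i in range(cfg.n_genera - 2)
    ]
    log_mu = rng.normal(4.0, 1.0, size=cfg.n_genera)
    lam = np.tile(np.exp(log_mu), (n, 1))
    # elevations scale with the global effect size (~55x and up to ~7x at
    # the default 2.5 SD) so a null config also nulls the microbiome marks
    lam[subtype == "viral", 0] *= np.exp(1.6 * cfg.effect_sd_units)
    lam[arm, 1] *= np.exp(0.8 * cfg.effect_sd_units * eff_u[arm])
    p_nb = cfg.nb_size / (cfg.nb_size + lam)
    counts = rng.negative_binomial(cfg.nb_size, p_nb)
    lib = counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    microbiome = np.log2(counts / lib * 1e6 + 1.0)

    # --- survival ----------------------------------------------------------
    hazard = cfg.base_hazard * np.array([HAZARD_MULTIPLIERS[s] for s in subtype])
    event_t = rng.exponential(1.0 / hazard)
    os_time, os_event = _censor(event_t, cfg.censor_frac, rng)

    labels = pd.DataFrame(
        {"hpv_status": np.where(subtype == "viral", "positive", "negative")},
        index=sample_ids,
    )
    clinical = ClinicalTable(sample_ids, os_time, os_event, labels)
    truth = CohortTruth(list(sample_ids), subtype, gradient_u, hazard)
    expr_m = OmicsMatrix(expression, sample_ids, gene_ids, "expression")
    meth_m = OmicsMatrix(methylation, sample_ids, probe_ids, "methylation")
    micro_m = OmicsMatrix(microbiome, sample_ids, genus_ids, "microbiome")
    return expr_m, meth_m, micro_m, clinical, truth


def _censor(event_t: np.ndarray, frac: float, rng: np.random.Generator):
    """Uniform(0, C) censoring with C calibrated to the target fraction."""
    if frac == 0:
        return event_t, np.ones(event_t.size, dtype=bool)
    u = rng.uniform(size=event_t.size)
    lo, hi = 1e-6, float(event_t.max()) * 100
    for _ in range(200):
        c = 0.5 * (lo + hi)
        censored = float((u * c < event_t).mean())
        if censored > frac:
            lo = c
        else:
            hi = c
    cens_t = u * 0.5 * (lo + hi)
    os_event = event_t <= cens_t
    return np.minimum(event_t, cens_t), os_event


def simulate_survival_pair(
    n_per_group: int, hazard_ratio: float, base_hazard: float, censor_frac: float, seed: int
):
    """Two-group survival draw for power studies: group B has
    ``hazard_ratio`` times the event rate of group A."""
    rng = np.random.default_rng(seed)
    haz = np.repeat([base_hazard, base_hazard * hazard_ratio], n_per_group)
    event_t = rng.exponential(1.0 / haz)
    times, events = _censor(event_t, censor_frac, rng)
    groups = np.repeat(["A", "B"], n_per_group)
    return times, events, groups


def make_toy_fixture():
    """Tiny deterministic 12-sample cohort with 3 extremely separated
    subtypes, for exact end-to-end tests."""
    cfg = SimConfig(
        n_per_group=4, n_genes=80, n_probes=40, n_genera=10,
        module_size=6, probe_module_size=8, effect_sd_units=8.0,
        gradient_amplitude=0.0, seed=20240)
    rng = np.random.default_rng(cfg.seed)
    n = 12
    sample_ids = [f"T{i:02d}" for i in range(n)]
    subtype = np.repeat(["alpha", "beta", "gamma"], 4)
    gene_ids = _gene_ids(cfg.n_genes)
    base = rng.normal(6.0, 1.0, size=cfg.n_genes)
    mean = np.tile(base, (n, 1))
    for k, s in enumerate(["alpha", "beta", "gamma"]):
        cols = np.arange(30 + k * cfg.module_size, 30 + (k + 1) * cfg.module_size)
        mean[np.ix_(subtype == s, cols)] += cfg.effect_sd_units
    expression = mean + rng.normal(0, 1.0, size=(n, cfg.n_genes))
    probe_ids = [f"cg{i:06d}" for i in range(cfg.n_probes)]
    logit = np.tile(rng.normal(0, 1.5, size=cfg.n_probes), (n, 1))
    logit[subtype == "gamma"] -= 4.0
    methylation = _sigmoid(logit + rng.normal(0, 0.5, size=(n, cfg.n_probes)))
    genus_ids = ["Alphapapillomavirus"] + [f"Genus{i:03d}" for i in range(9)]
    lam = np.tile(np.exp(rng.normal(4, 1, size=10)), (n, 1))
    lam[subtype == "alpha", 0] *= np.exp(5.0)
    p_nb = 5.0 / (5.0 + lam)
    counts = rng.negative_binomial(5.0, p_nb)
    lib = counts.sum(axis=1, keepdims=True).astype(float)
    microbiome = np.log2(counts / lib * 1e6 + 1.0)
    haz = np.where(subtype == "gamma", 3.0, 1.0) / 60.0
    event_t = rng.exponential(1.0 / haz)
    os_time, os_event = _censor(event_t, 0.25, rng)
    clinical = ClinicalTable(
        sample_ids, os_time, os_event,
        pd.DataFrame({"hpv_status": np.where(subtype == "alpha", "positive", "negative")},
                     index=sample_ids),
    )
    truth = CohortTruth(sample_ids, subtype, np.full(n, np.nan), haz)
    return (
        OmicsMatrix(expression, sample_ids, gene_ids, "expression"),
        OmicsMatrix(methylation, sample_ids, probe_ids, "methylation"),
        OmicsMatrix(microbiome, sample_ids, genus_ids, "microbiome"),
        clinical,
        truth,
    )


def group_recovery_ari(
    truth_labels: Sequence, predicted: Sequence, group) -> float:
    """How well one planted group is isolated: binary ARI between
    membership in ``group`` and membership in the predicted cluster that
    holds the plurality of the group's samples."""
    truth_labels = np.asarray(truth_labels)
    predicted = np.asarray(predicted)
    in_group = truth_labels == group
    if not in_group.any():
        raise ValueError(f"group {group!r} absent from truth")
    clusters, counts = np.unique(predicted[in_group], return_counts=True)
    majority = clusters[np.argmax(counts)]
    return float(adjusted_rand_score(in_group, predicted == majority))


def write_truth(truth: CohortTruth, path) -> None:
    pd.DataFrame(
        {
            "sample_id": truth.sample_ids,
            "subtype": truth.subtype,
            "gradient_u": truth.gradient_u,
            "hazard": truth.hazard,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
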