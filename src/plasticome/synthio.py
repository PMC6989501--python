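"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the sampling design of a two-arm dietary-intervention
microbiome sub-study: two diet arms (low-carb / low-fat), up to three daily
stool samples per subject in a pre-diet window ("BL") and again ten weeks into
the intervention ("W10"), sparse ASV count tables, lognormal per-sample
library sizes and multiple sequencing lanes.

Generative model (all randomness from one :func:`numpy.random.default_rng`
stream seeded from the config):

1. a global mean composition ``p ~ Dirichlet(base_concentration)``;
2. each subject's baseline log-composition is ``log p`` plus an i.i.d.
   ``Normal(0, sigma_between^2)`` per-taxon subject effect;
3. the composition on day ``d`` is ``softmax(baseline + eps_d)`` with
   ``eps_d ~ Normal(0, sigma_plasticity(subject)^2)`` i.i.d. per taxon per
   day — exchangeable perturbations about a subject centroid, not a random
   walk, so day-to-day plasticity is a well-defined subject-level trait;
4. the W10 window adds a diet-specific shift ``delta * v_diet *
   (subject dietary change / arm mean change)`` to the log-composition,
   where ``v_diet`` is a fixed unit direction per arm;
5. very-successful subjects carry signed ``da_effect`` log-scale shifts on
   ``n_da_taxa`` designated taxa (half effect for moderately successful) —
   the ground truth for differential-abundance power studies;
6. counts are ``Multinomial(depth, composition)`` with lognormal depth;
7. each sequencing lane applies a fixed multiplicative per-taxon bias
   ``exp(Normal(0, lane_bias_sd^2))`` to the composition before the draw.

Defaults mirror the emulated cohort: ~33 subjects per arm, 3-day windows,
library sizes ~74,000 +/- 33,000 reads, 1,000 taxa, 7 sequencing lanes, and a
Prevotella fraction rare enough that roughly half the subjects never detect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import (
    DIETS,
    RECALL_TIMEPOINTS,
    CohortMetadata,
    recall_column,
)

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_cohort", "fixture_small"]

#: success-category proportions used when assigning 12-month outcomes
_SUCCESS_CYCLE = ("US", "MS", "VS", "MS", "US", "MS", "VS", "VS", "US", "MS")

#: mean on-diet restricted %kcal by success category (VS change most)
_ONDIET_CENTER = {"US": 30.0, "MS": 23.0, "VS": 16.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``sigma_plasticity`` may be a scalar (shared by all subjects) or a vector
    with one entry per subject (both arms concatenated, low-carb first).
    """

    n_subjects_per_diet: int = 33
    n_taxa: int = 1000
    days_per_window: int = 3
    include_w10: bool = True
    depth_log_mean: float = 11.11  # exp -> ~74,000 reads
    depth_log_sd: float = 0.43
    base_concentration: float = 0.5
    sigma_between: float = 1.0
    sigma_plasticity: float | np.ndarray = 0.4
    delta_diet_shift: float = 1.0
    n_da_taxa: int = 0
    da_effect: float = 0.0
    n_lanes: int = 7
    lane_bias_sd: float = 0.1
    frac_prevotella: float = 0.01
    frac_bacteroides: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_diet < 1:
            raise ValueError("need at least one subject per diet")
        if self.n_taxa < 2:
            raise ValueError("need at least two taxa")
        if self.days_per_window < 1:
            raise ValueError("need at least one day per window")
        if self.depth_log_mean <= 0:
            raise ValueError("depth_log_mean must be positive (log reads)")
        for name in ("depth_log_sd", "sigma_between", "lane_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        sigma = np.atleast_1d(np.asarray(self.sigma_plasticity, dtype=float))
        if np.any(sigma < 0):
            raise ValueError("sigma_plasticity must be >= 0")
        n_subjects = 2 * self.n_subjects_per_diet
        if sigma.size not in (1, n_subjects):
            raise ValueError(
                f"sigma_plasticity must be scalar or length {n_subjects}, got {sigma.size}"
            )
        for name in ("frac_prevotella", "frac_bacteroides"):
            frac = getattr(self, name)
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_prevotella + self.frac_bacteroides > 1:
            raise ValueError("genus fractions sum above 1")
        if not 0 <= self.n_da_taxa <= self.n_taxa:
            raise ValueError("n_da_taxa must lie in [0, n_taxa]")
        if self.n_lanes < 1:
            raise ValueError("need at least one lane")

    def subject_sigmas(self) -> np.ndarray:
        sigma = np.atleast_1d(np.asarray(self.sigma_plasticity, dtype=float))
        if sigma.size == 1:
            sigma = np.repeat(sigma, 2 * self.n_subjects_per_diet)
        return sigma


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated cohort."""

    sigma_plasticity: pd.Series  # subject -> true daily turnover SD
    da_taxa: dict[str, float]  # taxon -> signed log-scale VS-US effect
    shift_magnitude: pd.Series  # subject -> true BL->W10 shift norm
    lane_bias: pd.DataFrame  # lanes x taxa multiplicative bias
    success: pd.Series  # subject -> US/MS/VS

    def to_json_dict(self) -> dict:
        return {
            "sigma_plasticity": self.sigma_plasticity.to_dict(),
            "da_taxa": self.da_taxa,
            "shift_magnitude": self.shift_magnitude.to_dict(),
            "lane_bias": {
                lane: self.lane_bias.loc[lane].to_dict() for lane in self.lane_bias.index
            },
            "success": self.success.to_dict(),
        }


def simulate_tree(n_taxa: int, seed: int, scale: float = 0.05) -> TreeNode:
    """Random rooted binary tree over tips ``ASV_1..ASV_n``.

    Topology and node depths follow a simple coalescent (uniform random
    joins, exponential waiting times); each branch is then perturbed by
    lognormal rate variation so the tree is not ultrametric, and rescaled so
    lengths are on a substitutions-per-site-like scale.  All lengths are
    strictly positive.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"ASV_{i + 1}", length=0.0) for i in range(n_taxa)]
    heights = [0.0] * n_taxa
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        h_r = heights.pop(j)
        h_l = heights.pop(i)
        left.length = t - h_l
        right.length = t - h_r
        parent = TreeNode(children=[left, right], length=0.0)
        nodes.append(parent)
        heights.append(t)
    root = nodes[0]
    root.length = None
    for node in root.traverse(include_self=False):
        node.length = max(node.length, 1e-9) * rng.lognormal(0.0, 0.3) * scale
    return root


def _assign_success(n: int) -> list[str]:
    return [_SUCCESS_CYCLE[i % len(_SUCCESS_CYCLE)] for i in range(n)]


def _draw_weight_loss(rng: np.random.Generator, category: str) -> float:
    low, high = {"US": (-3.0, 2.9), "MS": (3.0, 10.0), "VS": (10.1, 22.0)}[category]
    return float(np.round(rng.uniform(low, high), 2))


def simulate_cohort(config: SimConfig):
    """Simulate one cohort.

    Returns ``(counts, metadata, tree, taxonomy, truth)`` where ``counts`` is
    a samples x taxa integer DataFrame, ``metadata`` a
    :class:`~plasticome.io_formats.CohortMetadata`, ``tree`` a rooted
    :class:`skbio.TreeNode` over the taxa, ``taxonomy`` an ASV -> genus
    DataFrame and ``truth`` a :class:`SimTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_taxa = config.n_taxa
    taxa = [f"ASV_{i + 1}" for i in range(n_taxa)]

    tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31 - 1)))

    # --- taxonomy: a few named genera, the rest anonymous -----------------
    n_prev = int(round(config.frac_prevotella * n_taxa))
    n_bact = int(round(config.frac_bacteroides * n_taxa))
    n_prev = max(n_prev, 1) if config.frac_prevotella > 0 else 0
    n_bact = max(n_bact, 1) if config.frac_bacteroides > 0 else 0
    special = rng.choice(n_taxa, size=n_prev + n_bact, replace=False)
    genus = np.array([""] * n_taxa, dtype=object)
    genus[special[:n_prev]] = "Prevotella"
    genus[special[n_prev:]] = "Bacteroides"
    taxonomy = pd.DataFrame({"genus": genus}, index=pd.Index(taxa, name="asv_id"))

    # --- global composition ----------------------------------------------
    p = rng.dirichlet(np.full(n_taxa, config.base_concentration))
    p = np.maximum(p, 1e-12)
    if n_prev:
        # Prevotella rarity calibrated so the expected Prevotella count over
        # a subject's full set of samples is ~0.7 reads, leaving roughly half
        # the subjects with no detection at the configured depth.
        mean_depth = np.exp(config.depth_log_mean + config.depth_log_sd**2 / 2)
        samples_per_subject = config.days_per_window * (2 if config.include_w10 else 1)
        target = 0.7 / (mean_depth * samples_per_subject)
        prev_idx = special[:n_prev]
        current = p[prev_idx].sum()
        p[prev_idx] *= target / current
        p /= p.sum()
    log_p = np.log(p)

    # --- subjects ----------------------------------------------------------
    n_per = config.n_subjects_per_diet
    subject_ids, diets = [], []
    for diet_i, diet in enumerate(DIETS):
        tag = "LC" if diet == "low-carb" else "LF"
        for s in range(n_per):
            subject_ids.append(f"S{tag}{s + 1:02d}")
            diets.append(diet)
    n_subjects = len(subject_ids)
    success = _assign_success(n_per) * 2
    sigmas = config.subject_sigmas()
    sexes = rng.choice(["F", "M"], size=n_subjects)

    # DA taxa: drawn from the more abundant half so the designated log-scale
    # effect is expressible in counts rather than swallowed by zeros.
    da_taxa: dict[str, float] = {}
    da_vector = np.zeros(n_taxa)
    if config.n_da_taxa:
        abundant = np.argsort(p)[n_taxa // 2 :]
        chosen = rng.choice(abundant, size=config.n_da_taxa, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_da_taxa)
        for idx, sign in zip(chosen, signs):
            effect = float(sign * config.da_effect)
            da_taxa[taxa[idx]] = effect
            da_vector[idx] = effect

    # fixed per-diet shift direction on the log scale (unit norm)
    v_diet = {}
    for diet in DIETS:
        v = rng.normal(size=n_taxa)
        v_diet[diet] = v / np.linalg.norm(v)

    lanes = [f"L{i + 1}" for i in range(config.n_lanes)]
    lane_bias = np.exp(rng.normal(0.0, config.lane_bias_sd, size=(config.n_lanes, n_taxa)))

    # --- subject-level dietary recalls ------------------------------------
    subj_rows = {}
    change = np.zeros(n_subjects)
    for i, (sid, diet, cat) in enumerate(zip(subject_ids, diets, success)):
        restricted = "carb" if diet == "low-carb" else "fat"
        other = "fat" if restricted == "carb" else "carb"
        base_restricted = float(np.clip(rng.normal(45.0 if restricted == "carb" else 37.0, 6.0), 20, 70))
        ondiet = np.clip(
            rng.normal(_ONDIET_CENTER[cat], 4.0, size=3), 5, 60
        )
        protein = np.clip(rng.normal(17.0, 3.0, size=4), 5, 40)
        row = {
            "diet": diet,
            "sex": sexes[i],
            "weight_loss_pct_12mo": _draw_weight_loss(rng, cat),
        }
        for t_i, tp in enumerate(RECALL_TIMEPOINTS):
            r = base_restricted if tp == "baseline" else float(ondiet[t_i - 1])
            pr = float(protein[t_i])
            row[recall_column(restricted, tp)] = round(r, 2)
            row[recall_column(other, tp)] = round(max(100.0 - r - pr, 0.0), 2)
            row[recall_column("protein", tp)] = round(pr, 2)
        subj_rows[sid] = row
        change[i] = base_restricted - ondiet.mean()
    subjects = pd.DataFrame.from_dict(subj_rows, orient="index")
    subjects.index.name = "subject_id"

    # normalise change within arm for the W10 shift magnitude
    change_rel = np.empty(n_subjects)
    for diet in DIETS:
        mask = np.array(diets) == diet
        mean_change = change[mask].mean()
        change_rel[mask] = change[mask] / mean_change if mean_change != 0 else 1.0

    # --- samples -----------------------------------------------------------
    windows = ("BL", "W10") if config.include_w10 else ("BL",)
    sample_rows = {}
    counts = {}
    shift_mag = np.zeros(n_subjects)
    success_effect = {"US": 0.0, "MS": 0.5, "VS": 1.0}
    sample_counter = 0
    for i, (sid, diet, cat) in enumerate(zip(subject_ids, diets, success)):
        subj_effect = rng.normal(0.0, config.sigma_between, size=n_taxa)
        base_log = log_p + subj_effect + success_effect[cat] * da_vector
        shift_mag[i] = config.delta_diet_shift * change_rel[i]
        for window in windows:
            window_log = base_log.copy()
            if window == "W10":
                window_log = window_log + shift_mag[i] * v_diet[diet]
            for day in range(config.days_per_window):
                eps = rng.normal(0.0, sigmas[i], size=n_taxa)
                comp = np.exp(window_log + eps - (window_log + eps).max())
                lane_idx = sample_counter % config.n_lanes
                comp = comp * lane_bias[lane_idx]
                comp /= comp.sum()
                depth = max(int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sd))), 50)
                draw = rng.multinomial(depth, comp)
                day_offset = day if window == "BL" else 70 + day
                sample_id = f"{sid}_{window}_d{day_offset}"
                sample_rows[sample_id] = {
                    "subject_id": sid,
                    "window": window,
                    "day_offset": day_offset,
                    "lane": lanes[lane_idx],
                }
                counts[sample_id] = draw
                sample_counter += 1

    table = pd.DataFrame.from_dict(counts, orient="index", dtype=np.int64)
    table.columns = taxa
    table.index.name = "sample_id"
    samples = pd.DataFrame.from_dict(sample_rows, orient="index")
    samples.index.name = "sample_id"

    metadata = CohortMetadata(samples=samples, subjects=subjects)
    truth = SimTruth(
        sigma_plasticity=pd.Series(sigmas, index=subject_ids, name="sigma_plasticity"),
        da_taxa=da_taxa,
        shift_magnitude=pd.Series(shift_mag, index=subject_ids, name="shift_magnitude"),
        lane_bias=pd.DataFrame(lane_bias, index=lanes, columns=taxa),
        success=pd.Series(success, index=subject_ids, name="success"),
    )
    return table, metadata, tree, taxonomy, truth


_FIXTURE_CONFIG = SimConfig(
    n_subjects_per_diet=6,
    n_taxa=40,
    days_per_window=3,
    depth_log_mean=7.6,  # ~2,000 reads
    depth_log_sd=0.2,
    n_lanes=2,
    n_da_taxa=4,
    da_effect=1.5,
    frac_prevotella=0.05,
    frac_bacteroides=0.1,
    seed=20200129,
)


def fixture_small():
    """Deterministic tiny cohort (6 subjects/diet, 40 taxa, depth ~2,000)."""
    return simulate_cohort(replace(_FIXTURE_CONFIG))
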