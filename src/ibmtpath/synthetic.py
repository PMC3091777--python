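"""Synthetic studies with the statistical structure the analysis chain assumes.

The generator emulates a paired bilateral resistance-exercise design: every
subject contributes an exercised-arm and a control-arm sample at one recovery
time point, in four sex x time groups (defaults 3 male / 4 female subjects at
4 h and at 24 h, matching the sample sizes the pipeline is meant for), plus a
resting-state male-vs-female contrast carried by the control arms.

Per probe g the model is

    y_gj = a_g + z_subject(j) + delta_g * [arm_j = exercised]
              + gamma_g * [sex_j = F] + eps_gj,   eps_gj ~ N(0, sigma_g^2 / 2)

with mean intensity a_g ~ Uniform(intensity range), a subject random effect
z ~ N(0, subject_sd^2), an exercised-arm effect delta_g (the planted log2
fold change) and a sex shift gamma_g applied to all samples of female
subjects (so it shows in the unpaired baseline contrast and cancels exactly
in every within-subject paired contrast).  Gene variances follow the
scaled-inverse-chi-square prior the moderated t assumes,

    sigma_g^2 = d0_true * s0^2(a_g) / X,   X ~ chi^2(d0_true),

where sigma_g^2 is defined on the within-pair difference scale, so the
residual variance the paired analysis computes follows the prior exactly,

with a log-linear intensity trend s0^2(a) = s0_sq * exp(s0_slope * (a - ref))
(decreasing for negative slope, constant for slope 0).

Gene sets are drawn from the probe universe; a configurable fraction is
"loaded": their members receive coherent planted effects so the downstream
enrichment should flag them with the planted direction.  The toy term DAG
contains a (parent, single child) pair with >= 0.9 overlap and a
(parent, two siblings) triple exercising both branches of the collapse rule.
Ground truth for probes and sets is returned alongside the data.

Randomness contract: one root seed; independent named streams (intensity,
variance, effect assignment, subject effects, noise, sets, sex effects) are
spawned from it, so e.g. changing n_sets never perturbs the expression
matrix, and adding probes never perturbs subject effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study_model import ExpressionStudy
from .lrpath import GeneSet, GeneSetCollection
from .go_collapse import TermDag

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_study",
    "generate_gene_sets_and_dag",
    "generate_experiment",
    "generate_qpcr_panel",
]

#: names of the RNG streams spawned (in order) from the root seed
_STREAMS = ("intensity", "variance", "effects", "subjects", "noise", "sets", "sex_effects")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generator parameters; defaults are the design the pipeline targets.

    ``groups`` lists (sex, time, n_subjects); every subject yields an
    exercised and a control sample.  ``effect_size`` is the planted log2
    fold change delta of differentially expressed probes; ``de_fraction``
    the fraction of probes carrying it.  ``s0_sq`` is the prior variance
    scale at ``intensity_ref`` log2 units and ``s0_slope`` the log-linear
    trend per log2 intensity unit (negative = noisier low-intensity probes).
    ``loaded_fraction`` of the ``n_sets`` gene sets get coherent effects in
    ``within_set_de_fraction`` of their members.
    """

    seed: int
    n_probes: int = 20000
    groups: tuple[tuple[str, str, int], ...] = (
        ("M", "4h", 3), ("M", "24h", 3), ("F", "4h", 4), ("F", "24h", 4),
    )
    intensity_range: tuple[float, float] = (4.0, 14.0)
    d0_true: float = 4.0
    s0_sq: float = 0.05
    s0_slope: float = -0.25
    intensity_ref: float = 9.0
    subject_sd: float = 0.3
    de_fraction: float = 0.05
    effect_size: float = 1.0
    effect_size_range: tuple[float, float] | None = None
    sex_de_fraction: float = 0.02
    sex_effect_size: float = 1.0
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 200)
    loaded_fraction: float = 0.2
    within_set_de_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_probes < 1 or self.n_sets < 0:
            raise ValueError("counts must be positive")
        if not self.groups:
            raise ValueError("at least one group is required")
        for sex, time, n in self.groups:
            if n < 2:
                raise ValueError(
                    f"group ({sex}, {time}) has {n} subject(s); paired groups need >= 2"
                )
        for frac in (self.de_fraction, self.sex_de_fraction,
                     self.loaded_fraction, self.within_set_de_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.d0_true <= 0 or self.s0_sq <= 0 or self.subject_sd < 0:
            raise ValueError("d0_true and s0_sq must be positive, subject_sd >= 0")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid set size range")
        if hi > self.n_probes:
            raise ValueError(
                f"requested set size {hi} exceeds probe universe {self.n_probes}"
            )

    def probe_ids(self) -> pd.Index:
        return pd.Index([f"P{i + 1:06d}" for i in range(self.n_probes)], name="probe_id")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}

    def s0_sq_at(self, a: np.ndarray) -> np.ndarray:
        return self.s0_sq * np.exp(self.s0_slope * (np.asarray(a, float) - self.intensity_ref))


@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``probes``: per-probe frame (is_de, delta, direction, sex_de, sex_delta,
    a, sigma2, s0_sq_true).  ``sets``: per-set frame (is_loaded, direction,
    role) when sets were generated, else None.
    """

    probes: pd.DataFrame
    sets: pd.DataFrame | None = None


def _signed_effects(rng, n_probes, fraction, size, size_range=None):
    """Random sparse signed effect vector on a `fraction` of probes.

    Magnitudes are ``size`` (constant) or drawn uniformly from ``size_range``.
    """
    delta = np.zeros(n_probes)
    n_de = int(round(fraction * n_probes))
    if n_de:
        idx = rng.choice(n_probes, size=n_de, replace=False)
        mags = rng.uniform(*size_range, n_de) if size_range is not None else size
        delta[idx] = mags * rng.choice([-1.0, 1.0], size=n_de)
    return delta


def generate_study(
    config: SimulationConfig,
    probe_effects: np.ndarray | None = None,
    sex_effects: np.ndarray | None = None,
) -> tuple[ExpressionStudy, TruthTable]:
    """Simulate an expression study; effects may be supplied (e.g. set-loaded).

    ``probe_effects``/``sex_effects`` are signed per-probe log2 shifts; when
    None they are drawn from ``de_fraction``/``sex_de_fraction`` with random
    directions.  Deterministic given (config, seed).
    """
    rngs = config.rngs()
    n = config.n_probes
    probes = config.probe_ids()

    lo, hi = config.intensity_range
    a = rngs["intensity"].uniform(lo, hi, n)
    s0_true = config.s0_sq_at(a)
    sigma2 = config.d0_true * s0_true / rngs["variance"].chisquare(config.d0_true, n)

    if probe_effects is None:
        probe_effects = _signed_effects(rngs["effects"], n, config.de_fraction,
                                        config.effect_size, config.effect_size_range)
    else:
        probe_effects = np.asarray(probe_effects, dtype=float)
    if sex_effects is None:
        sex_effects = _signed_effects(rngs["sex_effects"], n, config.sex_de_fraction,
                                      config.sex_effect_size)
    else:
        sex_effects = np.asarray(sex_effects, dtype=float)

    design_rows = []
    columns = []
    col_is_ex = []
    col_is_f = []
    subject_of_col = []
    subjects = []
    for sex, time, n_subj in config.groups:
        for i in range(n_subj):
            subject = f"{sex}_{time}_{i + 1:02d}"
            subjects.append(subject)
            for arm, tag in (("exercised", "ex"), ("control", "ctl")):
                sample = f"{subject}_{tag}"
                design_rows.append((sample, subject, sex, arm, time))
                columns.append(sample)
                col_is_ex.append(arm == "exercised")
                col_is_f.append(sex == "F")
                subject_of_col.append(len(subjects) - 1)
    z = rngs["subjects"].normal(0.0, config.subject_sd, len(subjects))

    # sigma2 is defined on the within-pair difference scale (the scale the
    # paired analysis sees); each of the two independent per-sample noise
    # draws therefore carries half of it.
    sigma = np.sqrt(sigma2 / 2.0)
    values = np.empty((n, len(columns)))
    base = a  # mean intensity
    noise_rng = rngs["noise"]
    for j in range(len(columns)):
        eps = noise_rng.standard_normal(n) * sigma
        values[:, j] = (
            base
            + z[subject_of_col[j]]
            + (probe_effects if col_is_ex[j] else 0.0)
            + (sex_effects if col_is_f[j] else 0.0)
            + eps
        )

    design = (
        pd.DataFrame(design_rows, columns=["sample_id", "subject_id", "sex", "arm", "time"])
        .set_index("sample_id")
    )
    study = ExpressionStudy(
        values=pd.DataFrame(values, index=probes, columns=columns),
        design=design,
    )
    probe_truth = pd.DataFrame(
        {
            "is_de": probe_effects != 0,
            "delta": np.abs(probe_effects),
            "direction": np.sign(probe_effects),
            "sex_de": sex_effects != 0,
            "sex_delta": sex_effects,
            "a": a,
            "sigma2": sigma2,
            "s0_sq_true": s0_true,
        },
        index=probes,
    )
    return study, TruthTable(probes=probe_truth)


def generate_gene_sets_and_dag(
    config: SimulationConfig,
) -> tuple[GeneSetCollection, TermDag, pd.DataFrame]:
    """Gene sets over the probe universe plus a toy term DAG and set truth.

    The last five of the ``n_sets`` sets form the DAG: a parent with a single
    child covering >= 90% of it, and a parent with two heavily overlapping
    sibling children (each ~75% of the parent).  The remaining sets are flat;
    a ``loaded_fraction`` of them (round-robin up/down) are flagged as
    carrying coherent effects.
    """
    if config.n_sets < 6:
        raise ValueError("need n_sets >= 6 to accommodate the structured DAG sets")
    rng = config.rngs()["sets"]
    probes = np.asarray(config.probe_ids())
    lo, hi = config.set_size_range

    coll = GeneSetCollection()
    truth_rows = []
    n_flat = config.n_sets - 5
    n_loaded = int(round(config.loaded_fraction * n_flat))
    for k in range(n_flat):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(probes, size=size, replace=False))
        set_id = f"SET{k + 1:04d}"
        loaded = k < n_loaded
        direction = 0.0
        role = "null"
        if loaded:
            direction = 1.0 if k % 2 == 0 else -1.0
            role = "loaded"
        coll.add(GeneSet(set_id, f"synthetic set {k + 1}", tuple(members)))
        truth_rows.append((set_id, loaded, direction, role))

    # structured DAG sets: parent+single child, parent+two siblings
    def _fresh(size):
        return rng.choice(probes, size=size, replace=False)

    parent1 = _fresh(max(lo, min(hi, 40)))
    child1 = np.sort(parent1[: int(np.ceil(0.9 * len(parent1)))])
    parent2 = _fresh(max(lo, min(hi, 40)))
    k2 = int(np.ceil(0.75 * len(parent2)))
    child2a = np.sort(parent2[:k2])
    child2b = np.sort(parent2[len(parent2) - k2:])
    structured = [
        ("PARENT1", np.sort(parent1), "dag_parent_single_child"),
        ("CHILD1", child1, "dag_child"),
        ("PARENT2", np.sort(parent2), "dag_parent_siblings"),
        ("CHILD2A", child2a, "dag_sibling"),
        ("CHILD2B", child2b, "dag_sibling"),
    ]
    for set_id, members, role in structured:
        coll.add(GeneSet(set_id, role.replace("_", " "), tuple(members)))
        truth_rows.append((set_id, False, 0.0, role))

    dag = TermDag.from_edges(
        [("CHILD1", "PARENT1"), ("CHILD2A", "PARENT2"), ("CHILD2B", "PARENT2")]
    )
    sets_truth = (
        pd.DataFrame(truth_rows, columns=["set_id", "is_loaded", "direction", "role"])
        .set_index("set_id")
    )
    return coll, dag, sets_truth


def generate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, GeneSetCollection, TermDag, TruthTable]:
    """Full simulated experiment: sets drawn first, effects concentrated in them.

    Members of each loaded set become differentially expressed with
    probability ``within_set_de_fraction`` in the set's planted direction
    (first assignment wins for probes in several loaded sets); probes outside
    every loaded set carry background effects at rate ``de_fraction`` with
    random directions.  The study is then generated under those effects.
    """
    sets, dag, sets_truth = generate_gene_sets_and_dag(config)
    rng = config.rngs()["effects"]
    probes = config.probe_ids()
    pos = {p: i for i, p in enumerate(probes)}
    delta = np.zeros(config.n_probes)
    assigned = np.zeros(config.n_probes, dtype=bool)
    in_loaded = np.zeros(config.n_probes, dtype=bool)
    for set_id in sets_truth.index[sets_truth["is_loaded"]]:
        direction = sets_truth.loc[set_id, "direction"]
        idx = np.array([pos[g] for g in sets[set_id].members])
        in_loaded[idx] = True
        fresh = idx[~assigned[idx]]
        hit = fresh[rng.random(len(fresh)) < config.within_set_de_fraction]
        mags = (rng.uniform(*config.effect_size_range, len(hit))
                if config.effect_size_range is not None else config.effect_size)
        delta[hit] = mags * direction
        assigned[fresh] = True
    background = np.flatnonzero(~in_loaded)
    n_bg = int(round(config.de_fraction * len(background)))
    if n_bg:
        idx = rng.choice(background, size=n_bg, replace=False)
        mags = (rng.uniform(*config.effect_size_range, n_bg)
                if config.effect_size_range is not None else config.effect_size)
        delta[idx] = mags * rng.choice([-1.0, 1.0], size=n_bg)
    study, truth = generate_study(config, probe_effects=delta)
    truth.sets = sets_truth
    return study, sets, dag, truth


def generate_qpcr_panel(
    truth: TruthTable,
    n_genes: int = 10,
    n_subject_pairs: int = 2,
    seed: int = 0,
    noise_sd: float = 0.1,
    bio_sd: float = 0.25,
    comparisons: tuple[str, ...] = ("male_4h", "male_24h", "female_4h", "female_24h"),
    base_ct: float = 25.0,
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Duplicate-well Ct panel consistent with the planted expression truth.

    For each selected gene (differentially expressed probes preferred, padded
    with null probes) and each comparison, ``n_subject_pairs`` subjects get
    target and reference wells in both arms, analyzed in duplicate.  The
    exercised-arm target Ct is lowered by the planted log2 fold change (plus
    a per-subject biological deviation of sd ``bio_sd``); every well receives
    technical noise of sd ``noise_sd``; amplification efficiency is exactly
    2, so with zero noise the recovered fold is exactly 2**delta.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pt = truth.probes
    de = list(pt.index[pt["is_de"]])
    null = list(pt.index[~pt["is_de"]])
    genes = (de[: n_genes] + null[: max(0, n_genes - len(de))])[:n_genes]
    if len(genes) < n_genes:
        raise ValueError("not enough probes in truth table for the requested panel")

    gene_base = {g: base_ct + rng.normal(0.0, 2.0) for g in genes}
    rows = []
    for comp in comparisons:
        for s in range(n_subject_pairs):
            subject = f"{comp}_q{s + 1:02d}"
            for gene in genes:
                signed = pt.loc[gene, "delta"] * pt.loc[gene, "direction"]
                fold_log2 = signed + (rng.normal(0.0, bio_sd) if bio_sd > 0 else 0.0)
                # sample-wide shifts cancel through reference normalization
                shift = {arm: rng.normal(0.0, 0.5) for arm in ("exercised", "control")}
                ct_target = {
                    "control": gene_base[gene] + shift["control"],
                    "exercised": gene_base[gene] + shift["exercised"] - fold_log2,
                }
                ct_ref = {arm: reference_ct + shift[arm] for arm in shift}
                for arm in ("exercised", "control"):
                    for role, ct in (("target", ct_target[arm]), ("reference", ct_ref[arm])):
                        for _ in range(2):  # duplicate wells
                            noisy = ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                            rows.append((gene, comp, subject, arm, role, noisy))
    return pd.DataFrame(
        rows, columns=["gene", "comparison", "subject", "arm", "well_role", "ct"]
    )
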