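"""Synthetic MDD cohort generator with planted decision trees.

The study this pipeline reimplements published only cohort-level counts
(no subject-level feature table), so every downstream stage is exercised
on simulated cohorts that emulate the data structure: two cohorts of
depressed patients treated for eight weeks, a binary remission label
(HRSD17 <= 7 at week 8), 116 AAL gray-matter region volumes, 46 JHU
ICBM-DTI-81 tract FA values, and demographic/clinical covariates.

A *planted tree* is a chain of (feature, threshold) splits with per-leaf
subject counts and remission probabilities.  Subjects are first assigned
to leaves, then split-feature values are drawn from per-feature normal
distributions truncated to the leaf's side of each threshold, so the
planted node counts are reachable exactly.  All non-split ("noise")
features are drawn independently of the label.

Two label modes exist:

* ``exact_counts=False`` (default): each subject's label is a Bernoulli
  draw at its leaf's remission probability — node compositions match the
  planted probabilities up to binomial sampling error.
* ``exact_counts=True``: leaf compositions (remitters / non-remitters per
  leaf) are realized exactly, which lets worked examples reproduce
  published node counts by construction.  Used by
  :func:`default_paper_config`.

When a cohort plants one tree per modality, the two leaf memberships are
assigned independently conditional on the shared remission label.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import TREATMENT_ARMS, aal_regions, jhu_tracts

__all__ = [
    "PlantedLeaf",
    "PlantedSplit",
    "PlantedTreeSpec",
    "FeatureModel",
    "ClinicalModel",
    "CohortSpec",
    "CohortConfig",
    "simulate_cohort",
    "default_paper_config",
    "combination_reference_cohort",
    "GENERATOR_VERSION",
]

#: named, versioned RNG scheme recorded in run manifests
GENERATOR_VERSION = "roctree-cohort/1 (numpy PCG64, SeedSequence spawn per cohort)"

_DOMAIN = {"volumes": (0.0, np.inf), "fa": (0.0, 1.0)}


@dataclass(frozen=True)
class PlantedLeaf:
    count: int
    remission_p: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("leaf count must be non-negative")
        if not 0.0 <= self.remission_p <= 1.0:
            raise ValueError("remission probability must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedSplit:
    """One link of the planted chain.

    ``continue_side`` ('ge' or 'lt') is the branch the next split applies
    to; the opposite branch terminates in ``leaf``.
    """

    feature: str
    threshold: float
    continue_side: str
    leaf: PlantedLeaf

    def __post_init__(self) -> None:
        if self.continue_side not in ("ge", "lt"):
            raise ValueError("continue_side must be 'ge' or 'lt'")

    @property
    def stop_side(self) -> str:
        return "lt" if self.continue_side == "ge" else "ge"


@dataclass(frozen=True)
class PlantedTreeSpec:
    """An ordered chain of splits plus the final (deepest) leaf."""

    splits: tuple[PlantedSplit, ...]
    final_leaf: PlantedLeaf

    def __post_init__(self) -> None:
        object.__setattr__(self, "splits", tuple(self.splits))
        feats = [s.feature for s in self.splits]
        if len(set(feats)) != len(feats):
            raise ValueError("planted split features must be distinct")

    @property
    def n(self) -> int:
        return sum(s.leaf.count for s in self.splits) + self.final_leaf.count

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(s.feature for s in self.splits)

    @property
    def thresholds(self) -> list[float]:
        return [s.threshold for s in self.splits]

    def leaves(self) -> list[tuple[tuple[tuple[str, float, str], ...], PlantedLeaf]]:
        """(path conditions, leaf) pairs; conditions are (feature, thr, side)."""
        out = []
        prefix: list[tuple[str, float, str]] = []
        for s in self.splits:
            out.append((tuple(prefix + [(s.feature, s.threshold, s.stop_side)]), s.leaf))
            prefix.append((s.feature, s.threshold, s.continue_side))
        out.append((tuple(prefix), self.final_leaf))
        return out

    def validate(self, modality: str, n: int) -> None:
        atlas = aal_regions() if modality == "volumes" else jhu_tracts()
        for f in self.features:
            if f not in atlas:
                raise ValueError(f"unknown {modality} feature in planted tree: {f!r}")
        if self.n != n:
            raise ValueError(
                f"planted {modality} leaf counts sum to {self.n}, expected {n}")


@dataclass(frozen=True)
class FeatureModel:
    """Per-feature truncated-normal parameters for the synthetic features.

    Volumes are in mL (domain > 0); FA is unitless in [0, 1].  Defaults
    are generic; ``overrides`` center the planted split features on their
    thresholds so both branch sides are populated.
    """

    volume_mean: float = 10.0
    volume_sd: float = 2.5
    fa_mean: float = 0.50
    fa_sd: float = 0.07
    overrides: dict = field(default_factory=dict)  # feature -> (mean, sd)

    def params(self, feature: str, modality: str) -> tuple[float, float]:
        if feature in self.overrides:
            return tuple(self.overrides[feature])
        if modality == "volumes":
            return self.volume_mean, self.volume_sd
        return self.fa_mean, self.fa_sd


@dataclass(frozen=True)
class ClinicalModel:
    """Summary-statistic generators for the clinical covariates.

    Continuous covariates are normal (truncated to their valid range),
    binary ones Bernoulli; the week-8 HRSD17 is drawn conditional on the
    remission label so that remitted == (HRSD17 week 8 <= 7) holds by
    construction.  Doses are per treatment arm (mg/day).
    """

    age_mean: float = 33.0
    age_sd: float = 12.7
    hrsd_baseline_mean: float = 20.7
    hrsd_baseline_sd: float = 3.6
    week8_remit_mean: float = 4.6
    week8_remit_sd: float = 1.9
    week8_nonremit_mean: float = 12.8
    week8_nonremit_sd: float = 3.5
    female_p: float = 0.50
    melancholic_p: float = 0.22
    prior_treatment_p: float = 0.45
    dose: dict = field(default_factory=lambda: {
        "escitalopram": (13.0, 5.0),
        "sertraline": (61.0, 27.0),
        "venlafaxine": (100.0, 35.0),
    })


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: size, remission rate, planted trees, missingness."""

    name: str
    n: int
    remission_rate: float
    trees: dict = field(default_factory=dict)      # modality -> PlantedTreeSpec
    missing: dict = field(default_factory=dict)    # modality -> n subjects missing
    clinical: ClinicalModel = field(default_factory=ClinicalModel)

    def analysis_n(self, modality: str) -> int:
        """Subjects with the modality present (the per-analysis n)."""
        return self.n - int(self.missing.get(modality, 0))

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not 0.0 <= self.remission_rate <= 1.0:
            raise ValueError("remission rate must lie in [0, 1]")
        for mod in self.trees:
            if mod not in ("volumes", "fa"):
                raise ValueError(f"unknown modality {mod!r}")
            self.trees[mod].validate(mod, self.analysis_n(mod))
        if sum(self.missing.values()) > self.n:
            raise ValueError("more missing subjects than cohort size")


@dataclass(frozen=True)
class CohortConfig:
    cohorts: tuple[CohortSpec, ...]
    feature_model: FeatureModel = field(default_factory=FeatureModel)
    label_noise: float = 0.0
    exact_counts: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cohorts", tuple(self.cohorts))

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("config needs at least one cohort")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label noise must lie in [0, 1]")
        for c in self.cohorts:
            c.validate()

    def cohort(self, name: str) -> CohortSpec:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise KeyError(name)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _quota_assign(rng, indices: np.ndarray, quotas: Sequence[int]) -> list[np.ndarray]:
    """Randomly partition ``indices`` into groups of the given sizes."""
    if sum(quotas) != indices.size:
        raise ValueError("quotas inconsistent with pool size")
    perm = rng.permutation(indices)
    out, pos = [], 0
    for q in quotas:
        out.append(perm[pos:pos + q])
        pos += q
    return out


def _exact_labels(rng, spec: CohortSpec) -> tuple[np.ndarray, dict]:
    """Labels + per-tree leaf membership realizing leaf compositions exactly."""
    n = spec.n
    mods = list(spec.trees)
    # disjoint per-modality missing sets
    perm = rng.permutation(n)
    missing, pos = {}, 0
    for mod in mods:
        k = int(spec.missing.get(mod, 0))
        missing[mod] = np.sort(perm[pos:pos + k])
        pos += k
    complete = {mod: np.setdiff1d(np.arange(n), missing[mod]) for mod in mods}
    quotas = {
        mod: [(leaf.count, round(leaf.count * leaf.remission_p))
              for _, leaf in spec.trees[mod].leaves()]
        for mod in mods
    }
    r_tree = {mod: sum(r for _, r in quotas[mod]) for mod in mods}
    target_r = round(n * spec.remission_rate)

    remitted = np.zeros(n, dtype=bool)
    if len(mods) == 0:
        remitted[rng.choice(n, size=min(target_r, n), replace=False)] = True
    elif len(mods) == 1:
        mod = mods[0]
        k = missing[mod].size
        r_miss = int(np.clip(target_r - r_tree[mod], 0, k))
        if k:
            remitted[rng.choice(missing[mod], size=r_miss, replace=False)] = True
        # remitters inside the complete set are placed when leaves are filled
    else:
        m1, m2 = mods
        k1, k2 = missing[m1].size, missing[m2].size
        R1, R2 = r_tree[m1], r_tree[m2]
        n_shared = n - k1 - k2
        lo = max(0, R2 - R1, R2 - n_shared)
        hi = min(k1, k2 + R2 - R1, R2)
        if lo > hi:
            raise ValueError("planted leaf compositions are mutually infeasible")
        r_m1 = int(np.clip(target_r - R1, lo, hi))
        r_m2 = R1 - R2 + r_m1
        r_shared = R2 - r_m1
        if r_m1:
            remitted[rng.choice(missing[m1], size=r_m1, replace=False)] = True
        if r_m2:
            remitted[rng.choice(missing[m2], size=r_m2, replace=False)] = True
        shared = np.setdiff1d(np.arange(n), np.concatenate([missing[m1], missing[m2]]))
        if r_shared:
            remitted[rng.choice(shared, size=r_shared, replace=False)] = True

    if len(mods) == 1:
        # fill leaves first, deriving the labels of the complete set
        mod = mods[0]
        pool = complete[mod]
        counts = [c for c, _ in quotas[mod]]
        rquo = [r for _, r in quotas[mod]]
        rem_groups = _quota_assign(rng, pool, [sum(rquo), pool.size - sum(rquo)])
        remitted[rem_groups[0]] = True

    leaf_of = {}
    for mod in mods:
        pool = complete[mod]
        rpool = pool[remitted[pool]]
        npool = pool[~remitted[pool]]
        counts = [c for c, _ in quotas[mod]]
        rquo = [r for _, r in quotas[mod]]
        nquo = [c - r for c, r in quotas[mod]]
        if sum(rquo) != rpool.size or sum(nquo) != npool.size:
            raise ValueError("planted leaf compositions inconsistent with labels")
        r_groups = _quota_assign(rng, rpool, rquo)
        n_groups = _quota_assign(rng, npool, nquo)
        leaf = np.full(n, -1, dtype=int)
        for i, (rg, ng) in enumerate(zip(r_groups, n_groups)):
            leaf[rg] = i
            leaf[ng] = i
        leaf_of[mod] = leaf
    return remitted, {"missing": missing, "leaf_of": leaf_of}


def _bernoulli_labels(rng, spec: CohortSpec) -> tuple[np.ndarray, dict]:
    """Leaf-count partition + per-leaf Bernoulli labels (sampling mode)."""
    n = spec.n
    mods = list(spec.trees)
    perm = rng.permutation(n)
    missing, pos = {}, 0
    for mod in mods:
        k = int(spec.missing.get(mod, 0))
        missing[mod] = np.sort(perm[pos:pos + k])
        pos += k
    remitted = np.zeros(n, dtype=bool)
    leaf_of = {}
    if not mods:
        remitted = rng.random(n) < spec.remission_rate
        return remitted, {"missing": missing, "leaf_of": leaf_of}

    primary = mods[0]
    pool = np.setdiff1d(np.arange(n), missing[primary])
    leaves = spec.trees[primary].leaves()
    groups = _quota_assign(rng, pool, [leaf.count for _, leaf in leaves])
    leaf = np.full(n, -1, dtype=int)
    for i, g in enumerate(groups):
        leaf[g] = i
        remitted[g] = rng.random(g.size) < leaves[i][1].remission_p
    leaf_of[primary] = leaf
    off = missing[primary]
    remitted[off] = rng.random(off.size) < spec.remission_rate

    for mod in mods[1:]:
        # membership conditional on the shared label: P(leaf | label) is
        # proportional to the leaf's expected count of that label
        leaves = spec.trees[mod].leaves()
        pool = np.setdiff1d(np.arange(n), missing[mod])
        counts = np.array([leaf.count for _, leaf in leaves], dtype=float)
        probs = np.array([leaf.remission_p for _, leaf in leaves])
        leaf = np.full(n, -1, dtype=int)
        for label, w in ((True, counts * probs), (False, counts * (1 - probs))):
            sub = pool[remitted[pool] == label]
            if sub.size == 0:
                continue
            if w.sum() == 0:
                w = counts.copy()
            leaf[sub] = rng.choice(len(leaves), size=sub.size, p=w / w.sum())
        leaf_of[mod] = leaf
    return remitted, {"missing": missing, "leaf_of": leaf_of}


def _sample_features(rng, spec, fm: FeatureModel, assign) -> dict[str, np.ndarray]:
    """Draw every imaging feature column for one cohort."""
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    for mod, atlas in (("volumes", aal_regions()), ("fa", jhu_tracts())):
        lo, hi = _DOMAIN[mod]
        present = np.ones(n, dtype=bool)
        if mod in assign["missing"] and assign["missing"][mod].size:
            present[assign["missing"][mod]] = False
        elif spec.missing.get(mod):
            # modality has missing subjects but planted no tree: pick them now
            drop = rng.choice(n, size=int(spec.missing[mod]), replace=False)
            present[drop] = False
        tree = spec.trees.get(mod)
        constrained: dict[str, list] = {}
        if tree is not None:
            leaves = tree.leaves()
            leaf = assign["leaf_of"][mod]
            for f in tree.features:
                constrained[f] = [dict(
                    (feat, (thr, side)) for feat, thr, side in conds
                ).get(f) for conds, _ in leaves]
        for f in atlas:
            mean, sd = fm.params(f, mod)
            x = np.full(n, np.nan)
            if f in constrained:
                leaf = assign["leaf_of"][mod]
                for li, constraint in enumerate(constrained[f]):
                    sel = present & (leaf == li)
                    if not sel.any():
                        continue
                    if constraint is None:
                        x[sel] = _truncnorm(rng, mean, sd, lo, hi, int(sel.sum()))
                    else:
                        thr, side = constraint
                        a, b = (thr, hi) if side == "ge" else (lo, thr)
                        x[sel] = _truncnorm(rng, mean, sd, a, b, int(sel.sum()))
            else:
                x[present] = _truncnorm(rng, mean, sd, lo, hi, int(present.sum()))
            cols[f] = x
    return cols


def _sample_clinical(rng, spec: CohortSpec, remitted: np.ndarray) -> dict:
    cm = spec.clinical
    n = spec.n
    age = np.round(_truncnorm(rng, cm.age_mean, cm.age_sd, 18, 75, n), 1)
    sex = np.where(rng.random(n) < cm.female_p, "F", "M")
    base = np.clip(np.round(rng.normal(cm.hrsd_baseline_mean, cm.hrsd_baseline_sd, n)),
                   16, 34).astype(int)
    week8 = np.empty(n, dtype=int)
    r = remitted
    week8[r] = np.clip(np.round(_truncnorm(
        rng, cm.week8_remit_mean, cm.week8_remit_sd, -0.5, 7.49, int(r.sum()))), 0, 7)
    week8[~r] = np.clip(np.round(_truncnorm(
        rng, cm.week8_nonremit_mean, cm.week8_nonremit_sd, 7.51, 40.0,
        int((~r).sum()))), 8, 40)
    melancholic = rng.random(n) < cm.melancholic_p
    prior = rng.random(n) < cm.prior_treatment_p
    arm = rng.choice(TREATMENT_ARMS, size=n)
    dose = np.empty(n)
    for a in TREATMENT_ARMS:
        sel = arm == a
        mu, sd = cm.dose[a]
        if sel.any():
            dose[sel] = np.round(_truncnorm(rng, mu, sd, 1.0, np.inf, int(sel.sum())))
    return {
        "age": age, "sex": sex, "hrsd17_baseline": base, "hrsd17_week8": week8,
        "melancholic": melancholic, "prior_treatment": prior,
        "arm": arm, "dose_mg_day": dose,
    }


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the full multi-cohort subject table.

    One row per subject: ``subject_id, cohort, remitted``, 116 volume
    columns, 46 FA columns, clinical columns.  The seed (argument, else
    ``config.seed``) fully determines the output.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    frames = []
    for spec, child in zip(config.cohorts, ss.spawn(len(config.cohorts))):
        rng = np.random.default_rng(child)
        if config.exact_counts:
            remitted, assign = _exact_labels(rng, spec)
        else:
            remitted, assign = _bernoulli_labels(rng, spec)
        if config.label_noise > 0:
            flip = rng.random(spec.n) < config.label_noise
            remitted = remitted ^ flip
        cols = {
            "subject_id": [f"{spec.name}-{i + 1:03d}" for i in range(spec.n)],
            "cohort": spec.name,
            "remitted": remitted,
        }
        cols.update(_sample_features(rng, spec, config.feature_model, assign))
        cols.update(_sample_clinical(rng, spec, remitted))
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# --- canonical published structure ---------------------------------------

_LMF = "Frontal_Mid_L"
_RANG = "Angular_R"
_LCGC = "Cingulum_cingulate_gyrus_L"
_RSFOF = "Superior_fronto-occipital_fasciculus_R"
_RSLF = "Superior_longitudinal_fasciculus_R"


def _vol_tree(leaf_high, leaf_sel, leaf_low) -> PlantedTreeSpec:
    return PlantedTreeSpec(
        splits=(
            PlantedSplit(_LMF, 14.82, "lt", PlantedLeaf(*leaf_high)),
            PlantedSplit(_RANG, 6.25, "lt", PlantedLeaf(*leaf_sel)),
        ),
        final_leaf=PlantedLeaf(*leaf_low),
    )


def _dti_tree(leaf_cgc, leaf_sfof, leaf_slf, leaf_rest) -> PlantedTreeSpec:
    return PlantedTreeSpec(
        splits=(
            PlantedSplit(_LCGC, 0.63, "lt", PlantedLeaf(*leaf_cgc)),
            PlantedSplit(_RSFOF, 0.54, "lt", PlantedLeaf(*leaf_sfof)),
            PlantedSplit(_RSLF, 0.50, "ge", PlantedLeaf(*leaf_slf)),
        ),
        final_leaf=PlantedLeaf(*leaf_rest),
    )


def default_paper_config(seed: int | None = None) -> CohortConfig:
    """The canonical two-cohort configuration with the published structure.

    Test cohort: 80 treatment completers, 6 missing DTI (FA analysis
    n=74), 4 missing the T1 scan (volumetric analysis n=76).  Planted
    volumetric chain: left middle frontal gyrus at 14.82 mL then right
    angular gyrus at 6.25 mL, leaf compositions 25/33, 3/29, 7/14
    (remitters/subjects).  Planted FA chain: left cingulum (cingulate)
    0.63, right superior fronto-occipital fasciculus 0.54, right superior
    longitudinal fasciculus 0.50, leaf compositions 17/22, 2/20, 2/13 and
    the leftover node 13/19 implied by subtraction.  Validation cohort:
    83 subjects, remission 20/83; only its actionable-node compositions
    (7 remitters / 38 at the volumetric selected node; 4/13 and 1/6 at the
    FA nodes) are published, the remaining allocations are chosen
    consistent with the cohort totals.  Labels are realized exactly
    (``exact_counts=True``) so rule applications reproduce the node
    counts by construction.
    """
    test = CohortSpec(
        name="test",
        n=80,
        remission_rate=34 / 74,
        trees={
            "volumes": _vol_tree((33, 25 / 33), (29, 3 / 29), (14, 7 / 14)),
            "fa": _dti_tree((22, 17 / 22), (20, 2 / 20), (13, 2 / 13), (19, 13 / 19)),
        },
        missing={"volumes": 4, "fa": 6},
    )
    validation = CohortSpec(
        name="validation",
        n=83,
        remission_rate=20 / 83,
        trees={
            "volumes": _vol_tree((30, 11 / 30), (38, 7 / 38), (15, 2 / 15)),
            "fa": _dti_tree((30, 10 / 30), (13, 4 / 13), (6, 1 / 6), (34, 5 / 34)),
        },
        clinical=replace(ClinicalModel(), age_mean=35.5, age_sd=11.2,
                         hrsd_baseline_mean=22.3, hrsd_baseline_sd=3.4,
                         week8_remit_mean=5.2, week8_remit_sd=1.3,
                         week8_nonremit_mean=13.2, week8_nonremit_sd=3.8),
    )
    fm = FeatureModel(overrides={
        _LMF: (14.82, 2.0),
        _RANG: (6.25, 1.0),
        _LCGC: (0.63, 0.05),
        _RSFOF: (0.54, 0.05),
        _RSLF: (0.50, 0.05),
    })
    return CohortConfig(cohorts=(test, validation), feature_model=fm,
                        label_noise=0.0, exact_counts=True, seed=seed)


#: pooled overlap cell counts (volumetric-selected x FA-selected) implied by
#: inclusion-exclusion on the published serial/parallel combination counts
_OVERLAP_CELLS = {
    # (vol_selected, fa_selected): (n_nonremitters, n_remitters)
    (True, True): (10, 0),
    (True, False): (47, 10),
    (False, True): (6, 3),
    (False, False): (40, 41),
}


def combination_reference_cohort(seed: int | None = None) -> pd.DataFrame:
    """A pooled 157-subject cohort realizing the published rule overlap.

    Feature values are placed so that the volumetric rule (left middle
    frontal < 14.82 mL and right angular >= 6.25 mL) and the replicated FA
    rule (L-CgC < 0.63, R-SFOF < 0.54, R-SLF < 0.50) each select exactly
    the published pooled subject sets: 67 by the volumetric rule (57
    non-remitters), 19 by the FA rule (16 non-remitters), 10 non-remitters
    and no remitters in the intersection.  All other features are noise.
    """
    fm = default_paper_config().feature_model
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows_vol, rows_fa, remitted = [], [], []
    for (vol_sel, fa_sel), (n_nr, n_r) in _OVERLAP_CELLS.items():
        for is_rem in [False] * n_nr + [True] * n_r:
            rows_vol.append(vol_sel)
            rows_fa.append(fa_sel)
            remitted.append(is_rem)
    n = len(remitted)
    order = rng.permutation(n)
    vol_sel = np.array(rows_vol)[order]
    fa_sel = np.array(rows_fa)[order]
    remitted = np.array(remitted)[order]

    cols: dict[str, np.ndarray] = {}
    for f in aal_regions():
        mean, sd = fm.params(f, "volumes")
        cols[f] = _truncnorm(rng, mean, sd, 0, np.inf, n)
    for f in jhu_tracts():
        mean, sd = fm.params(f, "fa")
        cols[f] = _truncnorm(rng, mean, sd, 0, 1, n)

    def place(feature, modality, lo_mask_side):
        mean, sd = fm.params(feature, modality)
        lo, hi = _DOMAIN[modality]
        return mean, sd, lo, hi

    mean, sd, lo, hi = place(_LMF, "volumes", None)
    cols[_LMF][vol_sel] = _truncnorm(rng, mean, sd, lo, 14.82, int(vol_sel.sum()))
    cols[_LMF][~vol_sel] = _truncnorm(rng, mean, sd, 14.82, hi, int((~vol_sel).sum()))
    mean, sd, lo, hi = place(_RANG, "volumes", None)
    cols[_RANG][vol_sel] = _truncnorm(rng, mean, sd, 6.25, hi, int(vol_sel.sum()))
    mean, sd, lo, hi = place(_LCGC, "fa", None)
    cols[_LCGC][fa_sel] = _truncnorm(rng, mean, sd, lo, 0.63, int(fa_sel.sum()))
    cols[_LCGC][~fa_sel] = _truncnorm(rng, mean, sd, 0.63, hi, int((~fa_sel).sum()))
    mean, sd, lo, hi = place(_RSFOF, "fa", None)
    cols[_RSFOF][fa_sel] = _truncnorm(rng, mean, sd, lo, 0.54, int(fa_sel.sum()))
    mean, sd, lo, hi = place(_RSLF, "fa", None)
    cols[_RSLF][fa_sel] = _truncnorm(rng, mean, sd, lo, 0.50, int(fa_sel.sum()))

    spec = CohortSpec(name="pooled", n=n, remission_rate=float(remitted.mean()))
    out = {
        "subject_id": [f"pooled-{i + 1:03d}" for i in range(n)],
        "cohort": np.where(order < 74, "test", "validation"),
        "remitted": remitted,
    }
    out.update(cols)
    out.update(_sample_clinical(rng, spec, remitted))
    return pd.DataFrame(out)
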