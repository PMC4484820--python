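"""End-to-end workflow: fit on the test cohort, replicate, bootstrap.

Mirrors the study design: decision trees are fitted per modality on the
test cohort only; their actionable rules are then applied unchanged to
the validation cohort (exact binomial replication test against each
rule's fit accuracy, and chance test against the literature remission
rate); finally a multiple-sampling bootstrap on the pooled cohorts gives
the accuracy distribution of the best-covering tree, and the modality
trees are combined in series and in parallel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .apply import apply_rules, combine_parallel, combine_series, \
    extract_actionable_rules
from .atlas import CLINICAL_BINARY, CLINICAL_CONTINUOUS, TREATMENT_ARMS, \
    aal_regions, jhu_tracts
from .cohort import CohortConfig, simulate_cohort
from .io import RunManifest, cohort_config_to_dict, read_cohort, write_cohort
from .partition import DecisionTree, TreeNode, build_tree
from .stats import BootstrapResult, bootstrap_cv, evaluate_selection

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline",
           "feature_set", "render_tree"]

#: baseline-only clinical predictors admitted to the combined model
_CLINICAL_PREDICTORS = ("age", "hrsd17_baseline", "dose_mg_day",
                        "sex_female", "melancholic_bin", "prior_treatment_bin")


def feature_set(df: pd.DataFrame, modality: str) -> tuple[pd.DataFrame, list[str]]:
    """Resolve a modality name to (possibly augmented) table + feature list.

    ``volumes`` and ``fa`` use the packaged atlas columns present in the
    table; ``all`` adds baseline clinical/demographic predictors as raw
    values (binaries as 0/1, treatment arm one-hot).  Week-8 outcomes are
    never predictors.
    """
    if modality == "volumes":
        return df, [c for c in aal_regions() if c in df.columns]
    if modality == "fa":
        return df, [c for c in jhu_tracts() if c in df.columns]
    if modality != "all":
        raise ValueError(f"unknown modality {modality!r}")
    out = df.copy()
    feats = [c for c in list(aal_regions()) + list(jhu_tracts())
             if c in df.columns]
    if "sex" in df.columns:
        out["sex_female"] = (df["sex"] == "F").astype(float)
    for col in ("melancholic", "prior_treatment"):
        if col in df.columns:
            out[f"{col}_bin"] = df[col].astype(float)
    if "arm" in df.columns:
        for a in TREATMENT_ARMS:
            out[f"arm_{a}"] = (df["arm"] == a).astype(float)
            feats.append(f"arm_{a}")
    feats += [c for c in _CLINICAL_PREDICTORS if c in out.columns]
    return out, feats


def render_tree(tree: DecisionTree) -> str:
    """Plain-text rendering of the fitted hierarchy with node counts."""
    lines = []

    def walk(node: TreeNode, depth: int, label: str) -> None:
        tag = f"{label}n={node.n} R={node.n_remit} NR={node.n_nonremit} " \
              f"p_remit={node.p_remission:.2f}"
        lines.append("  " * depth + tag)
        if not node.is_leaf:
            c = node.cut
            lines.append("  " * depth +
                         f"split: {c.feature} >= {c.threshold:g} "
                         f"(kappa={c.kappa:.3f}, p={c.p_value:.2g}, "
                         f"NR-side={c.direction})")
            walk(node.children["ge"], depth + 1, "[>=] ")
            walk(node.children["lt"], depth + 1, "[< ] ")

    walk(tree.root, 0, "")
    return "\n".join(lines)


@dataclass
class PipelineConfig:
    simulate: CohortConfig | None = None
    test_path: str | None = None
    validation_path: str | None = None
    modalities: tuple[str, ...] = ("volumes", "fa")
    alpha: float = 0.01
    chance_remission: float = 0.35
    min_accuracy: float = 0.80
    bootstrap_iters: int = 1000
    bootstrap_size: int = 100
    seed: int | None = None
    strict_io: bool = True


@dataclass
class PipelineReport:
    trees: dict = field(default_factory=dict)          # modality -> DecisionTree
    rules: dict = field(default_factory=dict)          # modality -> [Rule]
    evaluations: list = field(default_factory=list)    # EvaluationResult dicts
    combinations: dict = field(default_factory=dict)
    bootstrap: BootstrapResult | None = None
    bootstrap_modality: str | None = None
    manifest: RunManifest | None = None
    cohort: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "trees": {m: t.to_dict() for m, t in self.trees.items()},
            "rules": {m: [str(r) for r in rs] for m, rs in self.rules.items()},
            "evaluations": [e.to_dict() for e in self.evaluations],
            "combinations": self.combinations,
            "bootstrap_modality": self.bootstrap_modality,
        }
        if self.bootstrap is not None:
            d["bootstrap"] = self.bootstrap.summary()
        return d

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        for m, t in self.trees.items():
            t.save(outdir / f"tree_{m}.json")
            (outdir / f"tree_{m}.txt").write_text(render_tree(t) + "\n")
        if self.evaluations:
            pd.DataFrame([e.to_dict() for e in self.evaluations]).to_csv(
                outdir / "evaluations.tsv", sep="\t", index=False)
        if self.bootstrap is not None:
            pd.DataFrame({
                "specificity": self.bootstrap.specificity,
                "coverage": self.bootstrap.coverage,
            }).to_csv(outdir / "bootstrap_iterations.tsv", sep="\t", index=False)
        if self.manifest is not None:
            self.manifest.save(outdir / "manifest.json")
        if self.cohort is not None:
            write_cohort(self.cohort, outdir / "cohort.csv")


def _rule_fit_accuracy(tree: DecisionTree, rule) -> float:
    for node in tree.root.walk():
        if node.node_id == rule.node_id:
            return node.p_nonremission
    raise KeyError(f"rule node {rule.node_id!r} not in tree")


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    report = PipelineReport()
    manifest = RunManifest(
        config={
            "modalities": list(config.modalities),
            "alpha": config.alpha,
            "chance_remission": config.chance_remission,
            "min_accuracy": config.min_accuracy,
            "bootstrap": {"iters": config.bootstrap_iters,
                          "size": config.bootstrap_size},
            "simulate": (cohort_config_to_dict(config.simulate)
                         if config.simulate else None),
        },
        seed=config.seed,
    )
    if config.simulate is not None:
        df = simulate_cohort(config.simulate, seed=config.seed)
        report.cohort = df
    else:
        if not (config.test_path and config.validation_path):
            raise ValueError("provide either a simulation config or both "
                             "test and validation cohort files")
        test_df = read_cohort(config.test_path, strict=config.strict_io)
        val_df = read_cohort(config.validation_path, strict=config.strict_io)
        manifest.record_input(config.test_path)
        manifest.record_input(config.validation_path)
        test_df = test_df.assign(cohort="test")
        val_df = val_df.assign(cohort="validation")
        df = pd.concat([test_df, val_df], ignore_index=True)
    report.manifest = manifest

    test = df[df["cohort"] == "test"]
    validation = df[df["cohort"] == "validation"]
    if len(test) == 0 or len(validation) == 0:
        raise ValueError("both a test and a validation cohort are required")

    for modality in config.modalities:
        fit_df, feats = feature_set(test, modality)
        tree = build_tree(fit_df, feats, alpha=config.alpha, fit_cohort="test")
        tree.metadata["modality"] = modality
        report.trees[modality] = tree
        rules = extract_actionable_rules(tree, min_accuracy=config.min_accuracy)
        report.rules[modality] = rules
        val_aug, _ = feature_set(validation, modality)
        for ri, rule in enumerate(rules):
            rid = f"{modality}:{rule.node_id}"
            fit_acc = _rule_fit_accuracy(tree, rule)
            sel_t = apply_rules([rule], feature_set(test, modality)[0])
            report.evaluations.append(evaluate_selection(
                sel_t, test, rule_id=rid, cohort="test",
                chance_remission=config.chance_remission))
            sel_v = apply_rules([rule], val_aug)
            report.evaluations.append(evaluate_selection(
                sel_v, validation, rule_id=rid, cohort="validation",
                reference_accuracy=min(fit_acc, 1.0 - 1e-9),
                chance_remission=config.chance_remission))

    with_rules = [m for m in config.modalities if report.rules[m]]
    pooled_by_mod = {m: feature_set(df, m)[0] for m in with_rules}
    if with_rules:
        # bootstrap the tree that covers the most pooled non-remitters
        def pooled_cov(m):
            return apply_rules(report.rules[m], pooled_by_mod[m]).n_nonremitters
        best = max(with_rules, key=pooled_cov)
        report.bootstrap_modality = best
        report.bootstrap = bootstrap_cv(
            pooled_by_mod[best], rules=report.rules[best],
            n_iter=config.bootstrap_iters,
            m=min(config.bootstrap_size, len(df)),
            seed=config.seed)
        for m in with_rules:
            sel = apply_rules(report.rules[m], pooled_by_mod[m])
            report.evaluations.append(evaluate_selection(
                sel, df, rule_id=f"{m}:all-rules", cohort="pooled",
                chance_remission=config.chance_remission))
    if len(with_rules) >= 2:
        a, b = with_rules[0], with_rules[1]
        merged = pooled_by_mod[a]
        for col in pooled_by_mod[b].columns:
            if col not in merged.columns:
                merged = merged.assign(**{col: pooled_by_mod[b][col]})
        ser = combine_series(report.rules[a], report.rules[b], merged)
        par = combine_parallel(report.rules[a], report.rules[b], merged)
        report.combinations = {
            "series": evaluate_selection(
                ser, df, rule_id=f"{a}&{b}", cohort="pooled",
                chance_remission=config.chance_remission).to_dict(),
            "parallel": evaluate_selection(
                par, df, rule_id=f"{a}|{b}", cohort="pooled",
                chance_remission=config.chance_remission).to_dict(),
        }
    return report
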