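"""The published decision trees as fixed, ready-to-apply objects.

These encode the test-cohort trees exactly as printed — features,
thresholds, directions and node compositions — so they can be applied to
new cohorts, combined, or bootstrapped without refitting.  Kappa values
are recomputed from the node tables; the stopping p-values of the
original analysis were not published, so the stored ``p_value`` is the
two-sided Fisher exact p of each node table.

Volumetric chain (fit n=76): left middle frontal gyrus volume at
14.82 mL, then right angular gyrus volume at 6.25 mL inside the
low-frontal branch; the actionable rule is the 26/29 non-remitter node.
FA chain (fit n=74): left cingulum (cingulate) at FA 0.63, right
superior fronto-occipital fasciculus at 0.54, right superior
longitudinal fasciculus at 0.50; two paths reach the 80% bar at fit
time, of which only the deep one replicated in the validation cohort.
"""
from __future__ import annotations

from .apply import Condition, Rule
from .partition import CutPoint, DecisionTree, TreeNode, kappa_2x2
from .stats import fisher_exact_2x2

__all__ = [
    "published_volumetric_tree",
    "published_dti_tree",
    "published_dti_replicated_rule",
]

LEFT_MIDDLE_FRONTAL = "Frontal_Mid_L"
RIGHT_ANGULAR = "Angular_R"
LEFT_CINGULUM_CG = "Cingulum_cingulate_gyrus_L"
RIGHT_SFOF = "Superior_fronto-occipital_fasciculus_R"
RIGHT_SLF = "Superior_longitudinal_fasciculus_R"


def _leaf(node_id: str, n_remit: int, n_nonremit: int) -> TreeNode:
    return TreeNode(node_id=node_id, n_remit=n_remit, n_nonremit=n_nonremit)


def _split(node_id: str, feature: str, threshold: float, direction: str,
           ge: TreeNode, lt: TreeNode) -> TreeNode:
    pos, neg = (ge, lt) if direction == "ge" else (lt, ge)
    table = ((pos.n_nonremit, pos.n_remit), (neg.n_nonremit, neg.n_remit))
    cut = CutPoint(
        feature=feature, threshold=threshold, direction=direction,
        table=table, kappa=kappa_2x2(table), p_value=fisher_exact_2x2(table),
    )
    return TreeNode(
        node_id=node_id,
        n_remit=ge.n_remit + lt.n_remit,
        n_nonremit=ge.n_nonremit + lt.n_nonremit,
        cut=cut,
        children={"ge": ge, "lt": lt},
    )


def published_volumetric_tree() -> DecisionTree:
    """The gray-matter volume tree: 25/33, 3/29 (actionable) and 7/14 leaves."""
    lt = _split(
        "root/lt", RIGHT_ANGULAR, 6.25, "ge",
        ge=_leaf("root/lt/ge", 3, 26),
        lt=_leaf("root/lt/lt", 7, 7),
    )
    root = _split(
        "root", LEFT_MIDDLE_FRONTAL, 14.82, "lt",
        ge=_leaf("root/ge", 25, 8),
        lt=lt,
    )
    return DecisionTree(
        root=root,
        features=(LEFT_MIDDLE_FRONTAL, RIGHT_ANGULAR),
        alpha=0.01,
        fit_cohort="test",
        metadata={"modality": "volumes", "source": "published test-cohort tree"},
    )


def published_dti_tree() -> DecisionTree:
    """The FA tree: 17/22, 2/20 and 2/13 leaves plus the 13/19 leftover."""
    slf = _split(
        "root/lt/lt", RIGHT_SLF, 0.50, "lt",
        ge=_leaf("root/lt/lt/ge", 13, 6),
        lt=_leaf("root/lt/lt/lt", 2, 11),
    )
    sfof = _split(
        "root/lt", RIGHT_SFOF, 0.54, "ge",
        ge=_leaf("root/lt/ge", 2, 18),
        lt=slf,
    )
    root = _split(
        "root", LEFT_CINGULUM_CG, 0.63, "lt",
        ge=_leaf("root/ge", 17, 5),
        lt=sfof,
    )
    return DecisionTree(
        root=root,
        features=(LEFT_CINGULUM_CG, RIGHT_SFOF, RIGHT_SLF),
        alpha=0.01,
        fit_cohort="test",
        metadata={"modality": "fa", "source": "published test-cohort tree"},
    )


def published_dti_replicated_rule() -> Rule:
    """The only FA path that replicated in the validation cohort."""
    return Rule(
        conditions=(
            Condition(LEFT_CINGULUM_CG, 0.63, "lt"),
            Condition(RIGHT_SFOF, 0.54, "lt"),
            Condition(RIGHT_SLF, 0.50, "lt"),
        ),
        source_tree="published-dti",
        node_id="root/lt/lt/lt",
    )
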