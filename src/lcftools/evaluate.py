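"""Five-way scoring of classifications and group-level rollups.

Each simulated read carries its GO term of origin, so its assignment
falls into exactly one category:

* ``unclassified`` — no assignment;
* ``exact`` — assigned term equals the origin term;
* ``root`` — assigned to the hierarchy root (a real but uninformative
  classification);
* ``related`` — assigned to a proper non-root ancestor of the origin:
  higher up the hierarchy but on the same root path;
* ``incorrect`` — anything else (siblings, cousins and, by default,
  descendants of the origin).

Summaries follow the benchmark-table convention: the unclassified and
classified percentages are over all reads, while the root / exact-or-
related / incorrect percentages are over *classified* reads only.
Classified counts can be rolled up into higher-level functional groups
(e.g. the direct children of the root — binding, catalytic activity,
antioxidant activity, ...) by summing each group's descendants, and
normalised to 0–1 proportions per sample for cross-sample comparison.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .tree_builder import FunctionTree

CATEGORIES = ("unclassified", "exact", "related", "root", "incorrect")


@dataclass
class EvaluationSummary:
    """Category counts plus the percentage columns of the benchmark
    table (denominators: total for (un)classified, classified for the
    rest)."""

    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0
    classified: int = 0
    pct_unclassified: float = 0.0
    pct_classified: float = 0.0
    pct_root: float = 0.0
    pct_exact: float = 0.0
    pct_related: float = 0.0
    pct_exact_or_related: float = 0.0
    pct_incorrect: float = 0.0
    #: True when no read was classified and the per-classified
    #: percentages are reported as 0 by convention.
    degenerate: bool = False


def categorize(
    assigned: str | None,
    origin: str,
    tree: FunctionTree,
    descendant_as_related: bool = False,
) -> str:
    """Assign one of the five evaluation categories.

    ``assigned=None`` means unclassified.  An assignment to a descendant
    of the origin counts as incorrect by default (the related category
    covers only terms higher up on the same root path);
    ``descendant_as_related=True`` offers the permissive reading for
    sensitivity analysis."""
    if origin not in tree:
        raise KeyError(f"origin term {origin!r} not in tree")
    if assigned is None:
        return "unclassified"
    if assigned not in tree:
        raise KeyError(f"assigned term {assigned!r} not in tree")
    if assigned == origin:
        return "exact"
    if assigned == tree.root:
        return "root"
    if tree.is_ancestor(assigned, origin):
        return "related"
    if descendant_as_related and tree.is_ancestor(origin, assigned):
        return "related"
    return "incorrect"


def summarize(
    categories: Iterable[str], root_as_unclassified: bool = False
) -> EvaluationSummary:
    """Aggregate per-read categories into counts and percentages.

    ``root_as_unclassified=True`` re-maps explicit root calls to the
    unclassified bucket (some classifiers emit root for no-evidence
    reads); the default keeps them classified."""
    counts = Counter(categories)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if root_as_unclassified:
        counts["unclassified"] += counts.pop("root", 0)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads to summarize")
    counts = {c: counts.get(c, 0) for c in CATEGORIES}
    classified = total - counts["unclassified"]
    summary = EvaluationSummary(
        counts=counts,
        total=total,
        classified=classified,
        pct_unclassified=100.0 * counts["unclassified"] / total,
        pct_classified=100.0 * classified / total,
        degenerate=classified == 0,
    )
    if classified:
        summary.pct_root = 100.0 * counts["root"] / classified
        summary.pct_exact = 100.0 * counts["exact"] / classified
        summary.pct_related = 100.0 * counts["related"] / classified
        summary.pct_exact_or_related = (
            100.0 * (counts["exact"] + counts["related"]) / classified
        )
        summary.pct_incorrect = 100.0 * counts["incorrect"] / classified
    return summary


def rollup(
    classified_counts: Mapping[str, int],
    tree: FunctionTree,
    group_terms: Iterable[str],
) -> dict[str, int]:
    """Sum classified read counts into functional groups: each group's
    total covers the group term itself plus all its descendants."""
    out: dict[str, int] = {}
    for group in group_terms:
        if group not in tree:
            raise KeyError(f"group term {group!r} not in tree")
        members = {group} | tree.descendants(group)
        out[group] = sum(classified_counts.get(t, 0) for t in members)
    return out


def normalize(group_counts: Mapping[str, int | float]) -> dict[str, float]:
    """Scale group counts to 0–1 proportions of their sum (per sample)."""
    total = float(sum(group_counts.values()))
    if total <= 0:
        raise ValueError("cannot normalize a zero total")
    if any(v < 0 for v in group_counts.values()):
        raise ValueError("negative counts")
    return {g: v / total for g, v in group_counts.items()}


def terms_at_depth(tree: FunctionTree, depth: int) -> list[str]:
    """All tree nodes at a given distance from the root (depth 1 = the
    level-2 groups directly under the root)."""
    return sorted(n for n, d in tree.depth.items() if d == depth)
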