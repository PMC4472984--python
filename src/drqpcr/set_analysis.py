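"""Root/leaf overlap of responsive genes, with mixed-pattern exclusion.

Genes whose per-timepoint calls point in opposite directions within a tissue
("mixed") are excluded from the overlap analysis entirely — even when the
other tissue shows a clean direction — mirroring how such genes are dropped
from published Venn diagrams. Membership is per (tissue, direction): a gene
cleanly up in one tissue and cleanly down in the other contributes to one
"-only" set of each direction family, so the two direction families are
independent two-set diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from drqpcr.responsiveness import ResponseCall


@dataclass(frozen=True)
class VennPartition:
    """Two two-set overlaps (up and down) plus the excluded mixed genes."""

    up_both: frozenset[str]
    up_root_only: frozenset[str]
    up_leaf_only: frozenset[str]
    down_both: frozenset[str]
    down_root_only: frozenset[str]
    down_leaf_only: frozenset[str]
    excluded_mixed: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in (
            "up_both",
            "up_root_only",
            "up_leaf_only",
            "down_both",
            "down_root_only",
            "down_leaf_only",
            "excluded_mixed",
        ):
            for gene in sorted(getattr(self, label)):
                rows.append({"gene_id": gene, "partition": label})
        return pd.DataFrame(rows, columns=["gene_id", "partition"])


def _patterns(calls: Mapping[str, ResponseCall] | Mapping[str, str]) -> dict[str, str]:
    out = {}
    for gene, call in calls.items():
        out[gene] = call.pattern if isinstance(call, ResponseCall) else call
    return out


def venn_partition(
    root_calls: Mapping[str, ResponseCall] | Mapping[str, str],
    leaf_calls: Mapping[str, ResponseCall] | Mapping[str, str],
) -> VennPartition:
    """Partition one cultivar's genes by (root pattern, leaf pattern).

    Accepts mappings gene -> ResponseCall (or bare pattern string). Genes
    mixed in either tissue go to ``excluded_mixed``; genes unchanged in both
    appear nowhere.
    """
    root = _patterns(root_calls)
    leaf = _patterns(leaf_calls)
    if set(root) != set(leaf):
        raise ValueError(
            "root and leaf call sets must cover the same genes; "
            f"difference: {set(root) ^ set(leaf)}"
        )
    excluded = {g for g in root if root[g] == "mixed" or leaf[g] == "mixed"}
    sets: dict[str, set[str]] = {
        k: set()
        for k in (
            "up_both",
            "up_root_only",
            "up_leaf_only",
            "down_both",
            "down_root_only",
            "down_leaf_only",
        )
    }
    for g in set(root) - excluded:
        for direction in ("up", "down"):
            in_root = root[g] == direction
            in_leaf = leaf[g] == direction
            if in_root and in_leaf:
                sets[f"{direction}_both"].add(g)
            elif in_root:
                sets[f"{direction}_root_only"].add(g)
            elif in_leaf:
                sets[f"{direction}_leaf_only"].add(g)
    return VennPartition(
        excluded_mixed=frozenset(excluded),
        **{k: frozenset(v) for k, v in sets.items()},
    )


def plot_venn(partition: VennPartition, path) -> None:
    """Optional two-circle figure per direction (plain matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, direction in zip(axes, ("up", "down")):
        only_r = len(getattr(partition, f"{direction}_root_only"))
        only_l = len(getattr(partition, f"{direction}_leaf_only"))
        both = len(getattr(partition, f"{direction}_both"))
        ax.add_patch(Circle((0.38, 0.5), 0.32, alpha=0.4, color="tab:brown"))
        ax.add_patch(Circle((0.62, 0.5), 0.32, alpha=0.4, color="tab:green"))
        ax.text(0.25, 0.5, str(only_r), ha="center", fontsize=14)
        ax.text(0.5, 0.5, str(both), ha="center", fontsize=14)
        ax.text(0.75, 0.5, str(only_l), ha="center", fontsize=14)
        ax.text(0.25, 0.88, "root", ha="center")
        ax.text(0.75, 0.88, "leaf", ha="center")
        ax.set_title(f"{direction}-regulated")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.axis("off")
    fig.suptitle(f"mixed-pattern genes excluded: {len(partition.excluded_mixed)}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
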