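"""ML tree search (NNI hill-climbing from a neighbor-joining start),
nonparametric bootstrap clade support, the genome-window support scan, and
support summarization onto a reference tree.

All randomness flows through a single integer seed; with the seed fixed every
search, replicate set and scan is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignments import Alignment, PartitionScheme, window_slice
from .likelihood import PartitionedData, TreeLikelihood, optimize_parameters
from .trees import (
    bipartitions,
    canonical_split,
    internal_edges,
    nj_tree,
    nni_neighbors,
    p_distance_matrix,
    parse_newick,
)


class SearchError(ValueError):
    pass


@dataclass
class CladeSet:
    """Named taxon subsets interpreted as unrooted bipartitions."""

    clades: dict[str, frozenset]

    def validate(self, taxa: list[str]) -> None:
        known = set(taxa)
        for name, clade in self.clades.items():
            if not clade or not clade < known:
                unknown = clade - known
                raise SearchError(
                    f"clade {name!r} must be a proper subset of the taxa"
                    + (f"; unknown: {sorted(unknown)}" if unknown else ""))


def _improve_by_nni(engine: TreeLikelihood, data: PartitionedData,
                    models: dict, current_lnl: float,
                    bl_tol: float) -> tuple[TreeLikelihood, float, bool]:
    """One NNI scan, first-improvement acceptance in deterministic edge order."""
    tree = engine.tree
    for edge_child in internal_edges(tree):
        for neighbor in nni_neighbors(tree, edge_child):
            cand = TreeLikelihood(data, neighbor, models)
            # one cheap screening sweep; accepted moves get a full refit
            cand.optimize_branch_lengths(tol=bl_tol, max_sweeps=1)
            cand_lnl = cand.lnl()
            if cand_lnl > current_lnl + 1e-6:
                cand.optimize_branch_lengths(tol=bl_tol, max_sweeps=10)
                return cand, cand.lnl(), True
    return engine, current_lnl, False


def ml_search(alignment: Alignment, scheme: PartitionScheme | None = None,
              models: dict | None = None, start_tree: dendropy.Tree | None = None,
              seed: int = 0, fit_models: bool = True,
              max_rounds: int = 50, bl_tol: float = 1e-3,
              ) -> tuple[dendropy.Tree, float, dict]:
    """Maximum-likelihood topology by NNI hill-climbing.

    Starts from ``start_tree`` or a neighbor-joining tree on p-distances;
    optionally fits substitution parameters once on the start tree (they are
    then held fixed during rearrangement, as the standard fast searches do).
    Returns (tree, lnL, fitted models); the returned lnL is never below the
    start tree's.
    """
    if alignment.ntaxa < 3:
        raise SearchError("tree search needs at least 3 taxa")
    if start_tree is None:
        start_tree = nj_tree(p_distance_matrix(alignment), alignment.taxa)
    data = PartitionedData(alignment, scheme)
    if models is None:
        models = data.default_models()
    if alignment.ntaxa == 3:
        engine = TreeLikelihood(data, start_tree, models)
        lnl = engine.optimize_branch_lengths(tol=bl_tol)
        return engine.sync_to_tree(), lnl, models
    if fit_models:
        models, start_tree, _, _ = optimize_parameters(
            start_tree, alignment, scheme, models, tol=0.1, max_passes=3)
    engine = TreeLikelihood(data, start_tree, models)
    lnl = engine.optimize_branch_lengths(tol=bl_tol)
    for _ in range(max_rounds):
        engine, lnl, improved = _improve_by_nni(engine, data, models, lnl, bl_tol)
        if not improved:
            break
    return engine.sync_to_tree(), lnl, models


def bootstrap_support(alignment: Alignment, scheme: PartitionScheme | None = None,
                      models: dict | None = None, n_reps: int = 100, seed: int = 0,
                      clades: CladeSet | None = None, partitioned: bool = False,
                      ) -> tuple[dict[str, float], dict[frozenset, float]]:
    """Nonparametric bootstrap frequencies of clades among replicate ML trees.

    Columns are resampled with replacement across the whole alignment, or
    within partitions when ``partitioned``. Substitution parameters are fitted
    once on the original data and held fixed across replicates; each replicate
    repeats the full topology search. Returns (named clade percentages, the
    full bipartition frequency table).
    """
    if n_reps < 1:
        raise SearchError("n_reps must be >= 1")
    if clades is not None:
        clades.validate(alignment.taxa)
    rng = np.random.default_rng(seed)
    if models is None:
        _, _, models = ml_search(alignment, scheme, seed=seed, fit_models=True,
                                 max_rounds=0)
    taxa_set = frozenset(alignment.taxa)
    counts: dict[frozenset, int] = {}
    ncols = alignment.ncols
    for _ in range(n_reps):
        if partitioned and scheme is not None:
            idx = np.empty(0, dtype=int)
            resampled_parts: dict[str, list[int]] = {}
            pos = 0
            for name, cols in scheme.partitions.items():
                cols0 = np.asarray(cols, dtype=int) - 1
                pick = rng.choice(cols0, size=len(cols0), replace=True)
                idx = np.concatenate([idx, pick])
                resampled_parts[name] = list(range(pos + 1, pos + len(cols0) + 1))
                pos += len(cols0)
            rep_scheme = PartitionScheme(resampled_parts,
                                         dict(scheme.encodings))
        else:
            idx = rng.choice(ncols, size=ncols, replace=True)
            rep_scheme = None
            if scheme is not None:
                labels = scheme.site_partition_labels(ncols)
                parts: dict[str, list[int]] = {}
                for new_col, old in enumerate(idx, start=1):
                    lab = labels[old]
                    if lab is not None:
                        parts.setdefault(lab, []).append(new_col)
                rep_scheme = PartitionScheme(parts, dict(scheme.encodings))
        rep_aln = alignment.columns(idx)
        tree, _, _ = ml_search(rep_aln, rep_scheme, models=models,
                               fit_models=False, seed=seed)
        for split in bipartitions(tree):
            counts[split] = counts.get(split, 0) + 1
    freqs = {split: 100.0 * n / n_reps for split, n in counts.items()}
    named: dict[str, float] = {}
    if clades is not None:
        for name, clade in clades.clades.items():
            named[name] = freqs.get(canonical_split(clade, taxa_set), 0.0)
    return named, freqs


@dataclass
class WindowScanResult:
    """Per-window clade bootstrap support along the genome."""

    table: pd.DataFrame  # window_start, window_end, width, partial, clade, support_pct

    def support(self, clade_name: str) -> pd.DataFrame:
        return self.table[self.table["clade"] == clade_name].reset_index(drop=True)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def clade_frequency_scan(alignment: Alignment, clades: CladeSet, width: int = 1000,
                         n_reps: int = 100, seed: int = 0,
                         min_width: int = 1, models: dict | None = None,
                         ) -> WindowScanResult:
    """Bootstrap clade support in consecutive non-overlapping genome windows.

    Each window is analyzed unpartitioned under a single GTR+I+G model (fitted
    on the window unless ``models`` provides one). Partial terminal windows
    are scanned but flagged.
    """
    clades.validate(alignment.taxa)
    rows = []
    rng = np.random.default_rng(seed)
    for win in window_slice(alignment, width):
        rep_seed = int(rng.integers(2 ** 31))
        named, _ = bootstrap_support(win.alignment, None, models=models,
                                     n_reps=n_reps, seed=rep_seed, clades=clades)
        for name, pct in named.items():
            rows.append({"window_start": win.start, "window_end": win.end,
                         "width": win.width, "partial": win.width < width,
                         "flagged_short": win.width < min_width,
                         "clade": name, "support_pct": pct})
    return WindowScanResult(pd.DataFrame(rows))


@dataclass
class SupportSummary:
    """Per-clade bootstrap percentage and posterior probability on one tree."""

    table: pd.DataFrame  # clade (sorted tuple), bs, bpp
    tree: dendropy.Tree

    def annotated_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True,
                                   suppress_rooting=True).strip()


def summarize_support(tree: dendropy.Tree,
                      bootstrap_freqs: dict[frozenset, float] | None = None,
                      posterior_clade_probs: dict[frozenset, float] | None = None,
                      ) -> SupportSummary:
    """Annotate each internal node of ``tree`` with BS/BPP labels.

    Clades absent from the replicate/posterior tables get support 0.
    """
    bootstrap_freqs = bootstrap_freqs or {}
    posterior_clade_probs = posterior_clade_probs or {}
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())

    def lookup(table, side, default=0.0):
        return table.get(canonical_split(side, taxa),
                         table.get(frozenset(side), default))

    rows = []
    for node in tree.postorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (1 < len(side) < len(taxa) - 1):
            continue
        bs = lookup(bootstrap_freqs, side)
        bpp = lookup(posterior_clade_probs, side)
        node.label = f"{bs:.0f}/{bpp:.2f}"
        rows.append({"clade": tuple(sorted(side)), "bs": bs, "bpp": bpp})
    return SupportSummary(pd.DataFrame(rows), tree)
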