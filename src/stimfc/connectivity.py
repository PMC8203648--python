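"""Differential functional-connectivity networks.

The FC stage of the analysis: global-mean removal from region time courses,
per-subject Pearson correlation matrices, Fisher-z pooling into group means,
dual-channel fixed-edge-count thresholding (the n strongest positive and n
most negative correlations, giving a fixed mean node degree k), per-edge
two-tailed Student's t tests between groups on Fisher-z values (P <= alpha,
uncorrected), signed net-FC counting over composite nodes, and
pseudo-directioning of composite edges from a directed
structural-connectivity prior ("synapses" forming on the target region).

Sign convention for differential edges: +1 when the treated group's
correlation exceeds the control group's, -1 when the control group's is
greater. A composite edge's net FC is the sum of its constituent signed
indicators over both channels, so e.g. seven control-greater plus one
treated-greater constituent connections give a net FC of -6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regional import RegionTimecourses

__all__ = [
    "FCMatrix",
    "ThresholdedFC",
    "DiffFCMatrix",
    "CompositeNetwork",
    "remove_global_mean",
    "fc_matrix",
    "group_mean_fc",
    "threshold_fc",
    "diff_fc",
    "aggregate_composite",
    "pseudo_direct",
    "compare_conditions",
]

CLIP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """Region x region Pearson correlations; symmetric, NaN diagonal.

    Entries undefined because a region's time course had zero variance are
    NaN and the regions listed in ``undefined_regions``.
    """

    values: pd.DataFrame
    undefined_regions: tuple[int, ...] = ()

    @property
    def regions(self) -> list[int]:
        return list(self.values.index)

    def restrict(self, regions) -> "FCMatrix":
        regions = list(regions)
        return FCMatrix(
            values=self.values.loc[regions, regions],
            undefined_regions=tuple(
                r for r in self.undefined_regions if r in set(regions)
            ),
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FCMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(int)
        return cls(values=df)


@dataclass
class ThresholdedFC:
    """Two disjoint edge sets over the selected regions.

    Each channel is a DataFrame with columns (a, b, r), a < b by region id.
    ``positive`` holds the retained strongest positive correlations
    (pCorrs), ``negative`` the most negative ones (nCorrs).
    """

    positive: pd.DataFrame
    negative: pd.DataFrame
    regions: tuple[int, ...]

    def degree(self, channel: str) -> float:
        """Mean node degree k = 2 x edges / regions for one channel."""
        edges = getattr(self, channel)
        return 2.0 * len(edges) / len(self.regions)

    def edge_set(self, channel: str) -> set[tuple[int, int]]:
        edges = getattr(self, channel)
        return {(int(a), int(b)) for a, b in zip(edges.a, edges.b)}


@dataclass
class DiffFCMatrix:
    """Signed significance indicators per region pair and channel.

    ``indicators[channel]`` is a symmetric region x region integer frame
    with entries -1 (control > treated), +1 (treated > control), 0 (not
    significant or not in the edge universe).
    """

    indicators: dict[str, pd.DataFrame]
    alpha: float
    test: str

    @property
    def regions(self) -> list[int]:
        return list(next(iter(self.indicators.values())).index)

    def nonzero_fraction(self) -> float:
        """Fraction of tested (in-universe) indicators that are nonzero."""
        tested = sig = 0
        for ch, mat in self.indicators.items():
            tri = np.triu_indices(len(mat), k=1)
            vals = mat.to_numpy()[tri]
            uni = self._universe.get(ch)
            if uni is None:
                tested += vals.size
            else:
                tested += len(uni)
            sig += int(np.sum(vals != 0))
        return sig / tested if tested else 0.0

    _universe: dict = field(default_factory=dict, repr=False)


@dataclass
class CompositeNetwork:
    """Aggregated net-FC edges between named composite nodes.

    ``net`` is a symmetric composite x composite integer frame of summed
    signed indicators; edges with |net| <= ``display_threshold`` are
    suppressed from ``edges()`` but retained in the matrix. Directions, when
    assigned from a structural prior, are "ab", "ba", "both", or None
    (undirected / no prior information).
    """

    net: pd.DataFrame
    display_threshold: int = 0
    directions: dict[tuple[str, str], str | None] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.net.index)

    def edges(self) -> list[dict]:
        out = []
        nodes = self.nodes
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                w = int(self.net.loc[u, v])
                if abs(w) > self.display_threshold:
                    out.append(
                        {
                            "source": u,
                            "target": v,
                            "net_fc": w,
                            "direction": self.directions.get((u, v)),
                        }
                    )
        return out

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e["source"], e["target"]) for e in self.edges()}

    def to_edgelist(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges(), columns=["source", "target", "net_fc", "direction"])

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges():
            u, v, d = e["source"], e["target"], e["direction"]
            if d == "ba":
                g.add_edge(v, u, net_fc=e["net_fc"], directed=True)
            elif d == "both":
                g.add_edge(u, v, net_fc=e["net_fc"], directed=True)
                g.add_edge(v, u, net_fc=e["net_fc"], directed=True)
            else:
                g.add_edge(u, v, net_fc=e["net_fc"], directed=d == "ab")
        nx.write_graphml(g, str(path))


def remove_global_mean(tc: RegionTimecourses) -> RegionTimecourses:
    """Subtract the cross-region mean from every region, per timepoint."""
    if tc.data.shape[0] < 2:
        raise ValueError("need at least two regions")
    data = tc.data - tc.data.mean(axis=0)
    return RegionTimecourses(
        data=data,
        n_active=tc.n_active,
        tr=tc.tr,
        subject=tc.subject,
        units=tc.units,
        omitted_regions=tc.omitted_regions,
    )


def fc_matrix(tc: RegionTimecourses) -> FCMatrix:
    """Pairwise Pearson correlations between full-length region time
    courses. Constant regions yield NaN entries and are flagged."""
    x = tc.data.to_numpy()
    if x.shape[1] < 3:
        raise ValueError("need at least three timepoints")
    sd = x.std(axis=1)
    undefined = [int(r) for r, s in zip(tc.data.index, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    np.fill_diagonal(r, np.nan)
    vals = pd.DataFrame(r, index=tc.data.index, columns=tc.data.index)
    return FCMatrix(values=vals, undefined_regions=tuple(undefined))


def fisher_z(r: np.ndarray | pd.DataFrame):
    """Fisher z-transform with clipping at |r| = 1 - 1e-7."""
    return np.arctanh(np.clip(r, -CLIP, CLIP))


def group_mean_fc(matrices: list[FCMatrix]) -> FCMatrix:
    """Fisher-z pooled group mean: entrywise tanh(mean(atanh(r))).

    Entries undefined in some subjects are averaged over the defined
    subset; entries undefined everywhere stay NaN.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    regions = matrices[0].regions
    for m in matrices[1:]:
        if m.regions != regions:
            raise ValueError("matrices must share region order")
    stack = np.stack([fisher_z(m.values.to_numpy()) for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_z = np.nanmean(stack, axis=0)
    out = np.tanh(mean_z)
    vals = pd.DataFrame(out, index=regions, columns=regions)
    undef = tuple(
        sorted(set().union(*(m.undefined_regions for m in matrices)))
    )
    return FCMatrix(values=vals, undefined_regions=undef)


def _ranked_pairs(values: pd.DataFrame):
    """Unique (a, b, r) pairs from the upper triangle, with stable order."""
    regions = list(values.index)
    arr = values.to_numpy()
    ia, ib = np.triu_indices(len(regions), k=1)
    r = arr[ia, ib]
    return (
        np.array([regions[i] for i in ia]),
        np.array([regions[j] for j in ib]),
        r,
    )


def threshold_fc(
    mean_fc: FCMatrix,
    regions=None,
    n_pos: int = 500,
    n_neg: int = 500,
) -> ThresholdedFC:
    """Keep the ``n_pos`` strongest positive and ``n_neg`` most negative
    correlations among the selected regions (dual-channel thresholding).

    With 100 selected regions and 500 edges per channel, the mean node
    degree per channel is the protocol's k = 10. Tie-breaking at the edge
    boundary is stable: |r| descending, then (a, b) ascending. If fewer
    edges are available than requested, all are kept with a warning.
    """
    if regions is None:
        regions = mean_fc.regions
    regions = list(regions)
    unknown = set(regions) - set(mean_fc.regions)
    if unknown:
        raise ValueError(f"regions not in matrix: {sorted(unknown)}")
    sub = mean_fc.restrict(regions)
    a, b, r = _ranked_pairs(sub.values)
    ok = np.isfinite(r)
    a, b, r = a[ok], b[ok], r[ok]

    def _top(sign: int, n: int) -> pd.DataFrame:
        m = r > 0 if sign > 0 else r < 0
        aa, bb, rr = a[m], b[m], r[m]
        order = np.lexsort((bb, aa, -np.abs(rr)))
        if n < len(order):
            order = order[:n]
        elif n > len(order):
            warnings.warn(
                f"only {len(order)} {'positive' if sign > 0 else 'negative'} "
                f"edges available of {n} requested; keeping all",
                stacklevel=3,
            )
        return pd.DataFrame({"a": aa[order], "b": bb[order], "r": rr[order]})

    return ThresholdedFC(
        positive=_top(+1, n_pos),
        negative=_top(-1, n_neg),
        regions=tuple(regions),
    )


def _subject_z(matrices: list[FCMatrix], pairs) -> np.ndarray:
    """(n_subjects, n_pairs) Fisher-z values."""
    index = matrices[0].values.index
    ii = index.get_indexer([a for a, _ in pairs])
    jj = index.get_indexer([b for _, b in pairs])
    out = np.empty((len(matrices), len(pairs)))
    for i, m in enumerate(matrices):
        out[i] = fisher_z(m.values.to_numpy()[ii, jj])
    return out


def diff_fc(
    group_a: list[FCMatrix],
    group_b: list[FCMatrix],
    edge_universe: tuple[ThresholdedFC, ThresholdedFC] | None = None,
    test: str = "homoscedastic",
    alpha: float = 0.05,
) -> DiffFCMatrix:
    """Per-edge differential FC test between two groups.

    For every edge in the universe (the union of both groups' thresholded
    channels; all pairs in both channels when no universe is given), a
    two-tailed Student's t test — homoscedastic, or paired for matched
    designs — compares the subjects' Fisher-z values. Significant edges
    (P <= alpha) receive +1 when the second (treated) group's correlation
    is greater, -1 when the first (control) group's is.
    """
    if test not in ("homoscedastic", "paired"):
        raise ValueError("test must be 'homoscedastic' or 'paired'")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two subjects per group")
    if test == "paired" and len(group_a) != len(group_b):
        raise ValueError("paired test requires equal group sizes")
    regions = group_a[0].regions
    for m in group_a + group_b:
        if m.regions != regions:
            raise ValueError("all matrices must share region order")

    if edge_universe is None:
        ia, ib = np.triu_indices(len(regions), k=1)
        allpairs = [(regions[i], regions[j]) for i, j in zip(ia, ib)]
        universe = {"positive": set(allpairs), "negative": set(allpairs)}
    else:
        ta, tb = edge_universe
        universe = {
            ch: ta.edge_set(ch) | tb.edge_set(ch)
            for ch in ("positive", "negative")
        }

    indicators: dict[str, pd.DataFrame] = {}
    for ch, pairs in universe.items():
        pairs = sorted(pairs)
        mat = pd.DataFrame(
            np.zeros((len(regions), len(regions)), dtype=int),
            index=regions,
            columns=regions,
        )
        if pairs:
            za = _subject_z(group_a, pairs)
            zb = _subject_z(group_b, pairs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if test == "homoscedastic":
                    res = stats.ttest_ind(
                        za, zb, axis=0, equal_var=True, nan_policy="omit"
                    )
                else:
                    res = stats.ttest_rel(za, zb, axis=0, nan_policy="omit")
            with np.errstate(invalid="ignore"):
                sig = res.pvalue <= alpha
            sign = np.sign(np.nanmean(zb, axis=0) - np.nanmean(za, axis=0))
            for (ra, rb), s, g in zip(pairs, sig, sign):
                if s and g != 0:
                    mat.loc[ra, rb] = int(g)
                    mat.loc[rb, ra] = int(g)
        indicators[ch] = mat
    out = DiffFCMatrix(indicators=indicators, alpha=alpha, test=test)
    out._universe = universe
    return out


def aggregate_composite(
    diff: DiffFCMatrix,
    membership: dict[int, str],
    display_threshold: int = 0,
) -> CompositeNetwork:
    """Sum signed indicators into composite-node net-FC edges.

    ``membership`` maps every region in ``diff`` to exactly one named
    composite node. Net FC for a composite pair is the sum over its
    constituent region pairs and both correlation channels (control-greater
    contributes -1, treated-greater +1). Within-composite indicators land on
    the matrix diagonal and are never displayed as edges.
    """
    regions = diff.regions
    missing = [r for r in regions if r not in membership]
    if missing:
        raise ValueError(f"membership does not cover regions {missing}")
    for r, c in membership.items():
        if isinstance(c, (list, tuple, set)):
            raise ValueError(
                f"region {r} maps to multiple composites {c}; membership "
                "must be disjoint"
            )
    comps = sorted({membership[r] for r in regions})
    net = pd.DataFrame(
        np.zeros((len(comps), len(comps)), dtype=int), index=comps, columns=comps
    )
    idx = {r: membership[r] for r in regions}
    for ch, mat in diff.indicators.items():
        arr = mat.to_numpy()
        ia, ib = np.triu_indices(len(regions), k=1)
        for i, j in zip(ia, ib):
            v = int(arr[i, j])
            if v:
                u, w = idx[regions[i]], idx[regions[j]]
                net.loc[u, w] += v
                if u != w:
                    net.loc[w, u] += v
    return CompositeNetwork(net=net, display_threshold=display_threshold)


def pseudo_direct(
    network: CompositeNetwork, prior: pd.DataFrame
) -> CompositeNetwork:
    """Assign edge directions from a directed structural prior.

    ``prior`` is a square 0/1 frame indexed by composite nodes; a nonzero
    entry (u, v) means a known anatomical projection u -> v. An edge u-v
    becomes directed u->v when only the u->v projection exists, stays
    bidirectional when both exist, and is left undirected (flagged None)
    when the prior has no entry.
    """
    directions: dict[tuple[str, str], str | None] = {}
    for e in network.edges():
        u, v = e["source"], e["target"]
        fwd = bool(
            u in prior.index and v in prior.columns and prior.loc[u, v]
        )
        rev = bool(
            v in prior.index and u in prior.columns and prior.loc[v, u]
        )
        if fwd and rev:
            directions[(u, v)] = "both"
        elif fwd:
            directions[(u, v)] = "ab"
        elif rev:
            directions[(u, v)] = "ba"
        else:
            directions[(u, v)] = None
    return CompositeNetwork(
        net=network.net,
        display_threshold=network.display_threshold,
        directions=directions,
    )


def compare_conditions(
    network_a: CompositeNetwork,
    network_b: CompositeNetwork,
    strength_a: pd.DataFrame | None = None,
    strength_b: pd.DataFrame | None = None,
) -> dict:
    """Edge-set overlap between two displayed networks, with an optional
    per-shared-edge strength comparison (group-mean |z|).

    ``strength_*`` are composite-level mean-|z| frames; for each shared
    edge the comparison reports which network's FC is stronger.
    """
    if set(network_a.nodes) != set(network_b.nodes):
        raise ValueError("networks must share the composite node space")
    ea, eb = network_a.edge_set(), network_b.edge_set()
    shared = sorted(ea & eb)
    out = {
        "overlap": len(shared),
        "n_a": len(ea),
        "n_b": len(eb),
        "shared_edges": shared,
    }
    if strength_a is not None and strength_b is not None:
        comp = {}
        for u, v in shared:
            sa = float(strength_a.loc[u, v])
            sb = float(strength_b.loc[u, v])
            comp[(u, v)] = "stronger" if sa > sb else ("weaker" if sa < sb else "equal")
        out["strength_a_vs_b"] = comp
    return out
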