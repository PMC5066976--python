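"""Clustering-accuracy metrics and comparison partitions.

Accuracy is measured per read: the precision of a read is the fraction of
its inferred cluster that truly belongs to its clonal family, and its
sensitivity is the fraction of its true family recovered in its inferred
cluster; sample-level numbers are means over reads, summarized by the F1
score (harmonic mean of mean precision and mean sensitivity).  A read
counts itself as correctly clustered, so a correct singleton scores 1 on
both axes (configurable).

Also here: intersection matrices between the largest clusters of two
partitions, the two synthetic error partitions used as interpretable
baselines (random singleton splitting; merging of families with nearly
identical true naive sequences), and the conventional annotation-based
clusterer that groups reads by V gene, J gene and CDR3 length and then
single-links at 90% CDR3 identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Partition, naive_hamming_fraction
from .hmm import Cluster


class EvaluationError(ValueError):
    pass


@dataclass
class ReadMetrics:
    """Per-read and sample-level clustering accuracy."""

    read_ids: list[str]
    precision: np.ndarray
    sensitivity: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def mean_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def f1(self) -> float:
        p, s = self.mean_precision, self.mean_sensitivity
        return 2 * p * s / (p + s) if p + s > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "precision": self.mean_precision,
            "sensitivity": self.mean_sensitivity,
            "f1": self.f1,
            "n_reads": len(self.read_ids),
        }


def per_read_metrics(truth: Partition, inferred: Partition, include_self: bool = True) -> ReadMetrics:
    """Per-read precision/sensitivity of ``inferred`` against ``truth``.

    For read x with true family T(x) and inferred cluster I(x):
    TP = |I(x) ∩ T(x)|, FP = |I(x) \\ T(x)|, FN = |T(x) \\ I(x)|, with x
    itself a member of both sets when ``include_self`` (the default, so a
    correctly isolated singleton scores precision = sensitivity = 1).
    """
    if truth.ids != inferred.ids:
        raise EvaluationError("partitions cover different read sets")
    true_sets = {rid: s for s in truth.as_sets() for rid in s}
    inf_sets = {rid: s for s in inferred.as_sets() for rid in s}
    ids = sorted(truth.ids)
    tp = np.zeros(len(ids))
    fp = np.zeros(len(ids))
    fn = np.zeros(len(ids))
    prec = np.zeros(len(ids))
    sens = np.zeros(len(ids))
    for k, rid in enumerate(ids):
        t, i = true_sets[rid], inf_sets[rid]
        if not include_self:
            t, i = t - {rid}, i - {rid}
        tp[k] = len(i & t)
        fp[k] = len(i - t)
        fn[k] = len(t - i)
        prec[k] = tp[k] / (tp[k] + fp[k]) if tp[k] + fp[k] else 1.0
        sens[k] = tp[k] / (tp[k] + fn[k]) if tp[k] + fn[k] else 1.0
    return ReadMetrics(ids, prec, sens, tp, fp, fn)


@dataclass
class IntersectionMatrix:
    """Normalized overlaps between the top-k clusters of two partitions:
    entry (i, j) is |intersection| divided by the mean of the two cluster
    sizes, so 1.0 means identical clusters."""

    sizes1: list[int]
    sizes2: list[int]
    matrix: np.ndarray

    def plot(self, ax=None, labels=("partition 1", "partition 2")):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.matrix, cmap="Blues", vmin=0, vmax=1)
        ax.set_xlabel(f"{labels[1]} clusters (size-ranked)")
        ax.set_ylabel(f"{labels[0]} clusters (size-ranked)")
        plt.colorbar(im, ax=ax, label="|intersection| / mean size")
        return ax


def _top_clusters(p: Partition, k: int) -> list[set[str]]:
    sets = p.as_sets()
    sets.sort(key=lambda s: (-len(s), tuple(sorted(s))))
    return sets[:k]


def intersection_matrix(p1: Partition, p2: Partition, k: int = 40) -> IntersectionMatrix:
    """Overlap matrix of the top-``k`` clusters by size (ties broken
    lexicographically) of two partitions over the same reads."""
    if p1.ids != p2.ids:
        raise EvaluationError("partitions cover different read sets")
    top1, top2 = _top_clusters(p1, k), _top_clusters(p2, k)
    m = np.zeros((len(top1), len(top2)))
    for i, a in enumerate(top1):
        for j, b in enumerate(top2):
            inter = len(a & b)
            if inter:
                m[i, j] = inter / ((len(a) + len(b)) / 2.0)
    return IntersectionMatrix([len(s) for s in top1], [len(s) for s in top2], m)


# ---------------------------------------------------------------------------
# synthetic comparison partitions


def synthetic_singleton(truth: Partition, fraction: float = 0.6, rng_seed=0) -> Partition:
    """Degrade the true partition by splitting a uniformly-chosen
    ``fraction`` of the reads into singleton clusters."""
    if not 0.0 <= fraction <= 1.0:
        raise EvaluationError("fraction outside [0, 1]")
    rng = np.random.default_rng(rng_seed)
    ids = sorted(truth.ids)
    n_split = int(np.floor(fraction * len(ids)))
    split = set(rng.choice(ids, size=n_split, replace=False)) if n_split else set()
    clusters = []
    for s in truth.as_sets():
        keep = sorted(s - split)
        if keep:
            clusters.append(Cluster(ids=tuple(keep), seqs=("",) * len(keep)))
        for rid in sorted(s & split):
            clusters.append(Cluster(ids=(rid,), seqs=("",)))
    return Partition(clusters=clusters)


def synthetic_neighbor(
    truth: Partition, true_naives: dict, threshold: float = 0.03, anchors: dict | None = None
) -> Partition:
    """Degrade the true partition by single-linkage merging of families
    whose true naive sequences differ by less than ``threshold`` in
    Hamming fraction (transitively closed).

    ``true_naives`` maps a representative read id (or family key matching
    cluster index order) to its naive sequence; anchors default to 0
    (equal-frame naives).
    """
    sets = truth.as_sets()
    keys = [tuple(sorted(s)) for s in sets]
    naives = []
    for key, s in zip(keys, sets):
        rep = next((rid for rid in key if rid in true_naives), None)
        if rep is None:
            raise EvaluationError(f"no naive sequence for family {key[:1]}")
        naives.append(true_naives[rep])
    anc = [0] * len(naives) if anchors is None else [
        anchors[next(r for r in k if r in anchors)] for k in keys
    ]
    # union-find over families
    parent = list(range(len(sets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            try:
                d = naive_hamming_fraction(naives[i], naives[j], max(anc[i], 0), max(anc[j], 0))
            except Exception:
                continue
            if d < threshold:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i, s in enumerate(sets):
        groups.setdefault(find(i), set()).update(s)
    clusters = [
        Cluster(ids=tuple(sorted(g)), seqs=("",) * len(g)) for g in groups.values()
    ]
    return Partition(clusters=clusters)


# ---------------------------------------------------------------------------
# the VJ CDR3 0.9 baseline


def vj_cdr3_baseline(annotations: dict, id_threshold: float = 0.9) -> Partition:
    """The conventional annotation-based clusterer.

    ``annotations`` maps read id to an :class:`~clonalfam.hmm.Annotation`
    (single best per read).  Reads are stratified by (V gene, J gene,
    CDR3 length); within a stratum, reads whose CDR3 nucleotide identity
    is at least ``id_threshold`` are single-linked into one cluster.
    Reads without CDR3 bounds become singletons.
    """
    strata: dict[tuple, list[str]] = {}
    cdr3s: dict[str, str] = {}
    singletons: list[str] = []
    for rid, ann in annotations.items():
        if ann.cdr3_start is None:
            singletons.append(rid)
            continue
        cdr3 = ann.naive_seq[ann.cdr3_start : ann.cdr3_end]
        cdr3s[rid] = cdr3
        strata.setdefault((ann.v_gene, ann.j_gene, len(cdr3)), []).append(rid)
    clusters: list[Cluster] = [Cluster(ids=(r,), seqs=("",)) for r in singletons]
    for key in sorted(strata):
        rids = sorted(strata[key])
        parent = list(range(len(rids)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(rids)):
            a = cdr3s[rids[i]]
            for j in range(i + 1, len(rids)):
                b = cdr3s[rids[j]]
                ident = sum(x == y for x, y in zip(a, b)) / len(a)
                if ident >= id_threshold:
                    parent[find(i)] = find(j)
        groups: dict[int, list[str]] = {}
        for i, rid in enumerate(rids):
            groups.setdefault(find(i), []).append(rid)
        for g in groups.values():
            clusters.append(Cluster(ids=tuple(sorted(g)), seqs=("",) * len(g)))
    return Partition(clusters=clusters)
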