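"""Agglomerative clonal-family inference.

Four modes, all agglomerative over inferred naive (unmutated ancestor)
sequences:

- **full**: merge criterion is the multi-HMM log likelihood ratio
  ``log P(A ∪ B) − log P(A) − log P(B)``; at each step the pair with the
  largest ratio is merged while the ratio exceeds a size-dependent
  threshold.  Naive-Hamming-fraction gates bracket the expensive
  likelihood work: pairs closer than the low gate (0.015) are merged
  outright, pairs farther than the high gate (0.08 at 5% sample mutation,
  rising to 0.15 at 20%) are never evaluated.
- **point**: the metric is the Hamming fraction between cluster Viterbi
  naive sequences (recomputed jointly after every merge), with a tighter
  dynamic threshold (0.035 at 5% mutation to 0.06 at 20%).
- **greedy**: each read's single-sequence Viterbi naive is computed once
  and clustered by greedy centroid assignment at half the point
  threshold (a fast, vsearch-style approximation).
- **seeded**: full-likelihood agglomeration restricted to merges
  involving the cluster that contains a user-chosen seed read; returns
  that one clonal family quickly even in large samples.

All modes are deterministic: ties break toward the lexicographically
smallest id pair.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .germline import GermlineSet
from .hmm import (
    Cluster,
    HmmModel,
    build_hmm,
    forward_logprob,
    pad_union_seqs,
    viterbi_annotate,
)
from .parameters import ParameterSet

INF = float("inf")

#: log likelihood ratio merge thresholds by candidate (merged) cluster
#: size; sizes of 6 and above use the size-6 value.  Natural log.
LLR_TABLE = {2: 18.0, 3: 16.0, 4: 15.0, 5: 14.0, 6: 13.0}


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# thresholds


def _interp(x: float, x0: float, y0: float, x1: float, y1: float) -> float:
    return y0 + (x - x0) * (y1 - y0) / (x1 - x0)


def dynamic_thresholds(sample_mut: float, mode: str = "full"):
    """Mutation-dependent naive-Hamming thresholds.

    full mode returns ``(lo, hi)``: merge-without-likelihood below
    ``lo`` (0.015 at any mutation level), never-evaluate above ``hi``
    (linear through 0.08 at 5% and 0.15 at 20% sample mutation, clamped
    to [0.015, 1]).  point mode returns the merge threshold (linear
    through 0.035 at 5% and 0.06 at 20%); greedy mode returns half the
    point threshold.
    """
    if not 0.0 <= sample_mut <= 1.0:
        raise ClusteringError(f"sample mutation fraction {sample_mut} outside [0, 1]")
    if mode == "full":
        hi = min(max(_interp(sample_mut, 0.05, 0.08, 0.20, 0.15), 0.015), 1.0)
        return (0.015, hi)
    point = min(max(_interp(sample_mut, 0.05, 0.035, 0.20, 0.06), 0.0), 1.0)
    if mode == "point":
        return point
    if mode == "greedy":
        return point / 2.0
    raise ClusteringError(f"unknown mode {mode!r}")


@dataclass
class ThresholdConfig:
    """All clustering thresholds in one place.

    The callables take the sample mutation fraction; the defaults
    reproduce :func:`dynamic_thresholds`.  ``greedy_id`` overrides the
    greedy threshold when set.
    """

    lo_naive_hf: float = 0.015
    hi_naive_hf: "callable" = staticmethod(lambda mut: dynamic_thresholds(mut, "full")[1])
    point_hf: "callable" = staticmethod(lambda mut: dynamic_thresholds(mut, "point"))
    greedy_id: float | None = None
    llr_table: dict[int, float] = field(default_factory=lambda: dict(LLR_TABLE))

    def llr_threshold(self, merged_size: int) -> float:
        return self.llr_table[min(max(merged_size, 2), max(self.llr_table))]

    def validate(self) -> "ThresholdConfig":
        for mut in (0.0, 0.05, 0.20, 0.5, 1.0):
            if not self.lo_naive_hf < self.hi_naive_hf(mut):
                raise ClusteringError(f"lo >= hi at mutation level {mut}")
        if any(v <= 0 for v in self.llr_table.values()):
            raise ClusteringError("log likelihood ratio thresholds must be positive")
        if not set(self.llr_table) >= {2, 3, 4, 5, 6}:
            raise ClusteringError("llr_table must cover sizes 2..6")
        return self


# ---------------------------------------------------------------------------
# naive Hamming fraction


def naive_hamming_fraction(naive_a: str, naive_b: str, anchor_a: int, anchor_b: int) -> float:
    """Hamming fraction between two naive sequences after aligning their
    conserved-cysteine anchors and padding both ends with N.

    Only positions where both bases are unambiguous count; raises if
    there are none.
    """
    if not 0 <= anchor_a < len(naive_a) or not 0 <= anchor_b < len(naive_b):
        raise ClusteringError("anchor outside sequence")
    anc = max(anchor_a, anchor_b)
    sa = "N" * (anc - anchor_a) + naive_a
    sb = "N" * (anc - anchor_b) + naive_b
    L = max(len(sa), len(sb))
    sa += "N" * (L - len(sa))
    sb += "N" * (L - len(sb))
    a = np.frombuffer(sa.encode(), dtype=np.uint8)
    b = np.frombuffer(sb.encode(), dtype=np.uint8)
    ok = (a != ord("N")) & (b != ord("N"))
    n = int(ok.sum())
    if n == 0:
        raise ClusteringError("no comparable positions")
    return float((a[ok] != b[ok]).sum() / n)


# ---------------------------------------------------------------------------
# partitions


@dataclass
class Partition:
    """Disjoint clusters covering a set of read ids."""

    clusters: list[Cluster]
    total_logprob: float | None = None
    merge_info: dict | None = None  # the merge that produced this step

    def __post_init__(self) -> None:
        ids = [i for c in self.clusters for i in c.ids]
        if len(ids) != len(set(ids)):
            raise ClusteringError("clusters overlap")

    @property
    def ids(self) -> set[str]:
        return {i for c in self.clusters for i in c.ids}

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {i: k for k, c in enumerate(self.clusters) for i in c.ids}

    def as_sets(self) -> list[set[str]]:
        return [set(c.ids) for c in self.clusters]

    @classmethod
    def from_membership(cls, member_of: dict[str, str]) -> "Partition":
        groups: dict[str, list[str]] = {}
        for rid, fam in member_of.items():
            groups.setdefault(str(fam), []).append(rid)
        clusters = [
            Cluster(ids=tuple(sorted(ids)), seqs=("",) * len(ids))
            for ids in groups.values()
        ]
        return cls(clusters=clusters)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"read_id": rid, "cluster_id": f"c{k}"}
            for k, c in enumerate(self.clusters)
            for rid in c.ids
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Partition":
        """Read a two-column membership CSV: read id, cluster/family id
        (the second column's name is free)."""
        import pandas as pd

        df = pd.read_csv(path, dtype=str)
        cols = list(df.columns)
        id_col = "read_id" if "read_id" in cols else cols[0]
        lab_col = next(c for c in cols if c != id_col)
        return cls.from_membership(dict(zip(df[id_col], df[lab_col])))


def sample_mutation_level(records) -> float:
    """Mean Smith-Waterman mutation fraction over annotatable reads; the
    quantity the dynamic thresholds depend on."""
    fracs = [r.sw.mut_fraction for r in records if r.sw is not None and r.sw.ok]
    return float(np.mean(fracs)) if fracs else 0.0


# ---------------------------------------------------------------------------
# the clustering engine


class _Engine:
    """Shared machinery: per-problem HMMs restricted to candidate genes,
    cluster construction with joint Viterbi naive sequences, and exact
    caches for models, marginals, naive distances and likelihood ratios."""

    def __init__(self, records, germline: GermlineSet, params: ParameterSet | None,
                 model: HmmModel | None = None, n_workers: int = 1):
        bad = [r.id for r in records if r.sw is None or not r.sw.ok]
        if bad:
            raise ClusteringError(f"unannotatable records: {bad[:5]}")
        if model is None and params is None:
            raise ClusteringError("need either a fixed model or a parameter set")
        self.records = {r.id: r for r in records}
        self.germline = germline
        self.params = params
        self.fixed_model = model
        self.n_workers = n_workers
        self._models: dict[tuple, HmmModel] = {}
        self._union_cache: dict[tuple, float] = {}
        self._nhf_cache: dict[tuple, float] = {}
        self._llr_cache: dict[tuple, float] = {}
        self.candidates: dict[tuple, dict[str, list[str]]] = {}

    # -- candidate genes -------------------------------------------------

    def _read_candidates(self, rec) -> dict[str, list[str]]:
        c = {r: list(rec.sw.candidates.get(r) or []) for r in "VDJ"}
        for region in "VDJ":
            if not c[region]:
                c[region] = self.germline.names(region)
        return c

    def _union_candidates(self, *clusters) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {r: [] for r in "VDJ"}
        for cl in clusters:
            for region, names in self.candidates[cl.ids].items():
                for n in names:
                    if n not in out[region]:
                        out[region].append(n)
        return {r: sorted(v) for r, v in out.items()}

    def model_for(self, cands: dict[str, list[str]]) -> HmmModel:
        if self.fixed_model is not None:
            return self.fixed_model
        key = tuple((r, tuple(cands[r])) for r in "VDJ")
        if key not in self._models:
            self._models[key] = build_hmm(self.params, self.germline, cands)
        return self._models[key]

    # -- cluster construction --------------------------------------------

    def _annotate_cluster(self, cluster: Cluster, cands) -> Cluster:
        model = self.model_for(cands)
        ann = viterbi_annotate(list(cluster.seqs), model, self.germline)
        cluster.naive_seq = ann.naive_seq
        cluster.naive_anchor = ann.cdr3_start
        self.candidates[cluster.ids] = cands
        return cluster

    def singleton(self, rid: str) -> Cluster:
        rec = self.records[rid]
        cluster = Cluster(
            ids=(rid,), seqs=(rec.work_seq,), anchor=rec.sw.v_anchor_read
        )
        return self._annotate_cluster(cluster, self._read_candidates(rec))

    def singletons(self) -> list[Cluster]:
        return [self.singleton(rid) for rid in sorted(self.records)]

    def merge(self, a: Cluster, b: Cluster, with_marginal: bool = True) -> Cluster:
        seqs, anc = pad_union_seqs(a, b)
        ids = a.ids + b.ids
        order = sorted(range(len(ids)), key=lambda i: ids[i])
        merged = Cluster(
            ids=tuple(ids[i] for i in order),
            seqs=tuple(seqs[i] for i in order),
            anchor=anc,
        )
        cands = self._union_candidates(a, b)
        self._annotate_cluster(merged, cands)
        if with_marginal:
            key = merged.ids
            if key not in self._union_cache:
                self._union_cache[key] = forward_logprob(
                    list(merged.seqs), self.model_for(cands)
                )
            merged.log_marginal = self._union_cache[key]
        return merged

    # -- pair metrics ----------------------------------------------------

    def marginal(self, cluster: Cluster) -> float:
        if cluster.log_marginal is None:
            model = self.model_for(self.candidates[cluster.ids])
            cluster.log_marginal = forward_logprob(list(cluster.seqs), model)
        return cluster.log_marginal

    def nhf(self, a: Cluster, b: Cluster) -> float:
        """Naive Hamming fraction between two clusters' naive sequences;
        infinite when either cluster has no usable CDR3 anchor."""
        key = (a.ids, b.ids) if a.ids < b.ids else (b.ids, a.ids)
        if key not in self._nhf_cache:
            if a.naive_anchor is None or b.naive_anchor is None:
                val = INF
            else:
                try:
                    val = naive_hamming_fraction(
                        a.naive_seq, b.naive_seq, a.naive_anchor, b.naive_anchor
                    )
                except ClusteringError:
                    val = INF
            self._nhf_cache[key] = val
        return self._nhf_cache[key]

    def llr(self, a: Cluster, b: Cluster) -> float:
        key = (a.ids, b.ids) if a.ids < b.ids else (b.ids, a.ids)
        if key not in self._llr_cache:
            la, lb = self.marginal(a), self.marginal(b)
            ukey = tuple(sorted(a.ids + b.ids))
            if ukey not in self._union_cache:
                seqs, _ = pad_union_seqs(a, b)
                model = self.model_for(self._union_candidates(a, b))
                self._union_cache[ukey] = forward_logprob(list(seqs), model)
            self._llr_cache[key] = self._union_cache[ukey] - la - lb
        return self._llr_cache[key]

    def llr_batch(self, pairs) -> None:
        """Evaluate many pair likelihood ratios, optionally on a worker
        pool; results land in the exact cache, so the outcome is
        independent of the worker count."""
        todo = [
            (a, b)
            for a, b in pairs
            if ((a.ids, b.ids) if a.ids < b.ids else (b.ids, a.ids)) not in self._llr_cache
        ]
        if self.n_workers > 1 and len(todo) > 1:
            with ThreadPoolExecutor(max_workers=self.n_workers) as pool:
                list(pool.map(lambda ab: self.llr(*ab), todo))
        else:
            for a, b in todo:
                self.llr(a, b)


def _pair_key(a: Cluster, b: Cluster):
    return (a.ids, b.ids) if a.ids < b.ids else (b.ids, a.ids)


def _total(clusters, engine) -> float:
    return float(sum(engine.marginal(c) for c in clusters))


# ---------------------------------------------------------------------------
# full likelihood mode


def agglomerate_full(
    records,
    model: HmmModel | None = None,
    thresholds: ThresholdConfig | None = None,
    *,
    germline: GermlineSet | None = None,
    params: ParameterSet | None = None,
    n_workers: int = 1,
) -> list[Partition]:
    """Full-likelihood agglomerative clustering.

    Returns the whole partition trajectory, one :class:`Partition` per
    merge (the first entry is the all-singleton partition); the last
    entry is the inferred clonal family partition under the stopping
    rule (no gated pair's likelihood ratio exceeds its size threshold).
    Each partition carries its total log probability, so other stopping
    points can be chosen post hoc.
    """
    thresholds = (thresholds or ThresholdConfig()).validate()
    engine = _Engine(records, germline, params, model, n_workers)
    mut = sample_mutation_level(records)
    lo = thresholds.lo_naive_hf
    hi = thresholds.hi_naive_hf(mut)
    clusters = engine.singletons()
    traj = [Partition(clusters=list(clusters), total_logprob=_total(clusters, engine))]
    while len(clusters) > 1:
        ordered = sorted(clusters, key=lambda c: c.ids)
        pairs = [
            (a, b)
            for i, a in enumerate(ordered)
            for b in ordered[i + 1 :]
        ]
        gated = [(a, b) for a, b in pairs if engine.nhf(a, b) <= hi]
        lo_pairs = [(a, b) for a, b in gated if engine.nhf(a, b) < lo]
        merge_pair = None
        merge_llr = None
        forced = False
        if lo_pairs:
            merge_pair = min(
                lo_pairs, key=lambda ab: (engine.nhf(*ab), _pair_key(*ab))
            )
            forced = True
        elif gated:
            engine.llr_batch(gated)
            best_llr = max(engine.llr(*ab) for ab in gated)
            tied = [ab for ab in gated if engine.llr(*ab) == best_llr]
            merge_pair = min(tied, key=lambda ab: _pair_key(*ab))
            size = len(merge_pair[0]) + len(merge_pair[1])
            if best_llr <= thresholds.llr_threshold(size):
                break
        if merge_pair is None:
            break
        a, b = merge_pair
        merge_llr = engine.llr(a, b)  # exact bookkeeping even for gate merges
        merged = engine.merge(a, b)
        clusters = [c for c in clusters if c is not a and c is not b] + [merged]
        traj.append(
            Partition(
                clusters=list(clusters),
                total_logprob=_total(clusters, engine),
                merge_info={
                    "merged": [list(a.ids), list(b.ids)],
                    "llr": merge_llr,
                    "forced_by_lo_gate": forced,
                },
            )
        )
    return traj


# ---------------------------------------------------------------------------
# point mode


def point_partition(
    records,
    model: HmmModel | None = None,
    thresholds: ThresholdConfig | None = None,
    *,
    germline: GermlineSet | None = None,
    params: ParameterSet | None = None,
) -> Partition:
    """Naive-point approximation: agglomerate on the Hamming fraction
    between cluster Viterbi naive sequences, recomputed jointly after
    every merge; no forward marginals are evaluated."""
    thresholds = (thresholds or ThresholdConfig()).validate()
    engine = _Engine(records, germline, params, model)
    thr = thresholds.point_hf(sample_mutation_level(records))
    clusters = engine.singletons()
    while len(clusters) > 1:
        ordered = sorted(clusters, key=lambda c: c.ids)
        best = None
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                d = engine.nhf(a, b)
                k = (d, _pair_key(a, b))
                if best is None or k < best[0]:
                    best = (k, a, b)
        (d, _), a, b = best
        if d >= thr:
            break
        merged = engine.merge(a, b, with_marginal=False)
        clusters = [c for c in clusters if c is not a and c is not b] + [merged]
    return Partition(clusters=clusters)


# ---------------------------------------------------------------------------
# greedy (vsearch-style) mode


def greedy_partition(
    records,
    model: HmmModel | None = None,
    thresholds: ThresholdConfig | None = None,
    *,
    germline: GermlineSet | None = None,
    params: ParameterSet | None = None,
    vsearch_path: str | None = None,
) -> Partition:
    """Greedy centroid clustering of single-read Viterbi naive sequences.

    Reads are processed in decreasing naive-length then lexicographic id
    order; each joins the first centroid within the greedy threshold,
    else founds a new centroid.  Runs internally by default; when
    ``vsearch_path`` is set the naive sequences are instead handed to an
    external vsearch executable in cluster_fast mode.
    """
    thresholds = (thresholds or ThresholdConfig()).validate()
    engine = _Engine(records, germline, params, model)
    thr = thresholds.greedy_id
    if thr is None:
        thr = dynamic_thresholds(sample_mutation_level(records), "greedy")
    singles = {c.ids[0]: c for c in engine.singletons()}
    if vsearch_path is not None:
        return _vsearch_cluster(singles, thr, vsearch_path)
    order = sorted(
        singles, key=lambda rid: (-len(singles[rid].naive_seq or ""), rid)
    )
    centroids: list[Cluster] = []
    members: dict[tuple, list[str]] = {}
    for rid in order:
        c = singles[rid]
        for cen in centroids:
            if engine.nhf(cen, c) < thr:
                members[cen.ids].append(rid)
                break
        else:
            centroids.append(c)
            members[c.ids] = [rid]
    clusters = []
    for cen in centroids:
        ids = tuple(sorted(members[cen.ids]))
        clusters.append(
            Cluster(ids=ids, seqs=tuple(engine.records[i].work_seq for i in ids))
        )
    return Partition(clusters=clusters)


def _vsearch_cluster(singles, thr, vsearch_path) -> Partition:
    """Shell out to a vsearch binary (optional; not required for any
    built-in functionality)."""
    import subprocess
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "naive.fasta"
        uc = Path(tmp) / "out.uc"
        with open(fasta, "w") as fh:
            for rid, c in singles.items():
                fh.write(f">{rid}\n{c.naive_seq}\n")
        subprocess.run(
            [vsearch_path, "--cluster_fast", str(fasta), "--id", str(1.0 - thr),
             "--uc", str(uc), "--maxaccept", "0", "--maxreject", "0"],
            check=True, capture_output=True,
        )
        member_of = {}
        for line in uc.read_text().splitlines():
            f = line.split("\t")
            if f[0] in ("S", "H"):
                member_of[f[8]] = f[8] if f[0] == "S" else f[9]
        return Partition.from_membership(member_of)


# ---------------------------------------------------------------------------
# seeded mode


def seeded_partition(
    records,
    seed_id: str,
    model: HmmModel | None = None,
    thresholds: ThresholdConfig | None = None,
    *,
    germline: GermlineSet | None = None,
    params: ParameterSet | None = None,
    n_workers: int = 1,
) -> Cluster:
    """Reconstruct only the clonal family containing ``seed_id``.

    Identical to full-mode agglomeration except that only merges
    involving the seed-containing cluster are ever evaluated; all other
    reads stay singletons unless absorbed by the seed cluster.
    """
    thresholds = (thresholds or ThresholdConfig()).validate()
    if all(r.id != seed_id for r in records):
        raise ClusteringError(f"unknown seed id {seed_id!r}")
    engine = _Engine(records, germline, params, model, n_workers)
    mut = sample_mutation_level(records)
    lo = thresholds.lo_naive_hf
    hi = thresholds.hi_naive_hf(mut)
    seed_cluster = engine.singleton(seed_id)
    others = [engine.singleton(rid) for rid in sorted(engine.records) if rid != seed_id]
    while others:
        gated = [c for c in others if engine.nhf(seed_cluster, c) <= hi]
        lo_cands = [c for c in gated if engine.nhf(seed_cluster, c) < lo]
        if lo_cands:
            best = min(lo_cands, key=lambda c: (engine.nhf(seed_cluster, c), c.ids))
        elif gated:
            engine.llr_batch([(seed_cluster, c) for c in gated])
            best_llr = max(engine.llr(seed_cluster, c) for c in gated)
            size = len(seed_cluster) + 1
            tied = [c for c in gated if engine.llr(seed_cluster, c) == best_llr]
            best = min(tied, key=lambda c: c.ids)
            if best_llr <= thresholds.llr_threshold(len(seed_cluster) + len(best)):
                break
        else:
            break
        others = [c for c in others if c is not best]
        seed_cluster = engine.merge(seed_cluster, best)
    return seed_cluster
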