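"""Synthetic repertoire generation with known ground truth.

A simulated repertoire is built family by family: a rearrangement event is
drawn from a :class:`~clonalfam.parameters.ParameterSet` (genes, erosion
lengths, junction insertions) to give a naive sequence; a birth-only (Yule)
tree with the requested number of leaves models the clonal expansion; the
naive sequence then evolves down the tree under per-site substitution, with
branch lengths scaled so each leaf hits its drawn target mutation fraction
in expectation.  Optionally each leaf receives a somatic indel.  The result
carries the true partition, annotations and indel records, so clustering
accuracy can be measured exactly.

Family sizes follow a configurable law: geometric (the default), Zipf
(power law), or a uniform "box".
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .germline import AnchorEroded, GermlineSet, cdr3_bounds
from .hmm import Annotation
from .parameters import ParameterSet

BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# family-size laws


@dataclass(frozen=True)
class SizeLaw:
    """Distribution of clonal family sizes (number of leaves).

    kinds:
      - ``geometric``: P(k) = (1 - 1/m)^(k-1) / m on {1, 2, ...} with mean
        ``m`` (param ``mean``);
      - ``zipf``: P(k) proportional to k^-s on {1..N} (params ``exponent``,
        ``n_max``);
      - ``box``: uniform on the integers [lo, hi] (params ``lo``, ``hi``).
    """

    kind: str
    mean: float | None = None
    exponent: float | None = None
    n_max: int | None = None
    lo: int | None = None
    hi: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "geometric":
            if self.mean is None or self.mean < 1:
                raise SimulationError("geometric law needs mean >= 1")
        elif self.kind == "zipf":
            if not (self.exponent and self.exponent > 0 and self.n_max and self.n_max >= 1):
                raise SimulationError("zipf law needs exponent > 0 and n_max >= 1")
        elif self.kind == "box":
            if self.lo is None or self.hi is None or not 1 <= self.lo <= self.hi:
                raise SimulationError("box law needs 1 <= lo <= hi")
        else:
            raise SimulationError(f"unknown size law {self.kind!r}")

    def _zipf_probs(self) -> np.ndarray:
        k = np.arange(1, self.n_max + 1, dtype=float)
        w = k ** (-self.exponent)
        return w / w.sum()

    def expected_size(self) -> float:
        if self.kind == "geometric":
            return float(self.mean)
        if self.kind == "zipf":
            p = self._zipf_probs()
            return float((np.arange(1, self.n_max + 1) * p).sum())
        return (self.lo + self.hi) / 2.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "geometric":
            if self.mean == 1:
                return np.ones(n, dtype=int)
            return rng.geometric(1.0 / self.mean, size=n)
        if self.kind == "zipf":
            return rng.choice(np.arange(1, self.n_max + 1), size=n, p=self._zipf_probs())
        return rng.integers(self.lo, self.hi + 1, size=n)


def sample_cluster_sizes(law: SizeLaw, n_target_seqs: int, rng_seed) -> list[int]:
    """Sizes for a repertoire aiming at ``n_target_seqs`` total reads: the
    target divided by the law's expected size gives the number of families,
    whose sizes are then drawn i.i.d. from the law."""
    if n_target_seqs < 1:
        raise SimulationError("n_target_seqs must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n_families = int(np.ceil(n_target_seqs / law.expected_size()))
    return [int(s) for s in law.sample(n_families, rng)]


# ---------------------------------------------------------------------------
# rearrangement sampling


def _draw(rng: np.random.Generator, dist: np.ndarray) -> int:
    return int(rng.choice(len(dist), p=np.asarray(dist, dtype=float)))


def sample_rearrangement(
    params: ParameterSet, germline: GermlineSet, rng: np.random.Generator
) -> tuple[str, Annotation]:
    """Draw one rearrangement event and assemble its naive sequence.

    Genes are drawn by usage; each gene end's erosion comes from that
    gene's own length distribution; junction insertion lengths and bases
    from the boundary distributions.  Events whose erosions destroy a
    conserved anchor codon or consume a whole D gene are rejected and
    redrawn (at most 10^4 times).
    """
    for _ in range(10_000):
        genes = {}
        for region in ("V", "D", "J"):
            names = list(params.gene_usage[region])
            probs = np.array([params.gene_usage[region][n] for n in names])
            genes[region] = names[_draw(rng, probs)]
        v, d, j = (germline[genes[r]] for r in ("V", "D", "J"))
        v3 = _draw(rng, params.erosion_dists["v_3p"][v.name])
        d5 = _draw(rng, params.erosion_dists["d_5p"][d.name])
        d3 = _draw(rng, params.erosion_dists["d_3p"][d.name])
        j5 = _draw(rng, params.erosion_dists["j_5p"][j.name])
        if v3 >= len(v.seq) or j5 >= len(j.seq) or d5 + d3 >= len(d.seq):
            continue
        if v.anchor + 3 > len(v.seq) - v3 or j5 > j.anchor:
            continue  # anchor eroded: non-functional, redraw
        inserts = {}
        for boundary in ("vd", "dj"):
            n_ins = _draw(rng, params.insertion_len_dists[boundary])
            comp = np.asarray(params.insertion_base_comp[boundary], dtype=float)
            inserts[boundary] = "".join(rng.choice(BASES, size=n_ins, p=comp))
        naive = (
            v.seq[: len(v.seq) - v3]
            + inserts["vd"]
            + d.seq[d5 : len(d.seq) - d3]
            + inserts["dj"]
            + j.seq[j5:]
        )
        ann = Annotation(
            v_gene=v.name,
            d_gene=d.name,
            j_gene=j.name,
            erosions=(v3, d5, d3, j5),
            vd_insertion=inserts["vd"],
            dj_insertion=inserts["dj"],
            naive_seq=naive,
        )
        try:
            ann.cdr3_start, ann.cdr3_end = cdr3_bounds(ann, germline)
        except AnchorEroded:
            continue
        return naive, ann
    raise SimulationError("rejection sampling failed 10^4 times; check parameters")


# ---------------------------------------------------------------------------
# clonal trees and somatic hypermutation


def _yule_tree(n_leaves: int, rng: np.random.Generator):
    """Birth-only tree with unit birth rate.

    Returns ``(parent, blen, leaves)``: parent indices (root = -1), branch
    lengths, and the node ids of the leaves.
    """
    parent = [-1]
    blen = [0.0]
    active = [0]
    birth = [0.0]  # time at which each active lineage started
    t = 0.0
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / k)
        split = active.pop(int(rng.integers(k)))
        blen[split] = t - birth[split]
        for _ in range(2):
            parent.append(split)
            blen.append(0.0)
            birth.append(t)
            active.append(len(parent) - 1)
    k = len(active)
    t_end = t + rng.exponential(1.0 / k)
    for node in active:
        blen[node] = t_end - birth[node]
    return np.array(parent), np.array(blen), list(active)


@dataclass
class SimulatedEvent:
    """One clonal family with full truth: the rearrangement annotation,
    the naive sequence, and the mutated (and optionally indel-bearing)
    leaf reads."""

    annotation: Annotation
    naive_seq: str
    n_leaves: int
    leaf_ids: list[str]
    leaf_seqs: list[str]  # post-substitution, pre-indel
    raw_seqs: list[str]  # observed reads (indels applied, if any)
    mut_fractions: list[float]
    indels: dict[str, list] = field(default_factory=dict)


def _jc_branch_probs(t: float, site_rates: np.ndarray) -> np.ndarray:
    """Per-site substitution probability on a branch of length ``t`` under
    Jukes-Cantor with relative site rates (mean 1)."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * t * site_rates))


def _target_to_branch_scale(f: float) -> float:
    """Observed divergence target -> expected substitutions per site
    (inverts the Jukes-Cantor saturation curve)."""
    f = min(f, 0.70)
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * f)


def simulate_family(
    naive_seq: str,
    annotation: Annotation,
    n_leaves: int,
    mut_fraction_dist,
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
    id_prefix: str = "fam",
) -> SimulatedEvent:
    """Expand one rearrangement into a mutated clonal family.

    A Yule tree with ``n_leaves`` leaves is simulated; each leaf draws a
    target mutation fraction from ``mut_fraction_dist`` (a callable taking
    the rng, or an array sampled uniformly); root-to-leaf path lengths are
    rescaled so each leaf's expected divergence from the naive sequence
    matches its target; sites mutate under Jukes-Cantor with relative
    per-site rate factors.
    """
    if n_leaves < 1:
        raise SimulationError("n_leaves must be >= 1")
    L = len(naive_seq)
    if site_rates is None:
        site_rates = np.ones(L)
    site_rates = np.asarray(site_rates, dtype=float)
    site_rates = site_rates / max(site_rates.mean(), 1e-12)

    parent, blen, leaves = _yule_tree(n_leaves, rng)

    def draw_target():
        if callable(mut_fraction_dist):
            return float(mut_fraction_dist(rng))
        arr = np.asarray(mut_fraction_dist, dtype=float)
        return float(arr[rng.integers(arr.size)])

    targets = {leaf: draw_target() for leaf in leaves}
    # depth of every node, including the root branch (naive -> first split)
    depth = np.zeros(len(parent))
    depth[0] = blen[0]
    for node in range(1, len(parent)):
        depth[node] = depth[parent[node]] + blen[node]
    # per-leaf branch-length multiplier, then per-branch multiplier as the
    # mean over the leaves below the branch (shared history compromise)
    leaf_scale = {
        leaf: (_target_to_branch_scale(targets[leaf]) / depth[leaf] if depth[leaf] > 0 else 0.0)
        for leaf in leaves
    }
    below: dict[int, list[int]] = {node: [] for node in range(len(parent))}
    for leaf in leaves:
        node = leaf
        while node != -1:
            below[node].append(leaf)
            node = parent[node]

    seq_idx = np.array([_BASE_IDX[b] for b in naive_seq], dtype=np.int8)
    node_seqs: dict[int, np.ndarray] = {-1: seq_idx}  # -1 = the naive cell
    order = sorted(range(len(parent)), key=lambda n: depth[n])
    for node in order:
        scale = float(np.mean([leaf_scale[leaf] for leaf in below[node]])) if below[node] else 0.0
        p = _jc_branch_probs(blen[node] * scale, site_rates)
        seq = node_seqs[parent[node]].copy()
        hits = np.flatnonzero(rng.random(L) < p)
        if hits.size:
            seq[hits] = (seq[hits] + rng.integers(1, 4, size=hits.size)) % 4
        node_seqs[node] = seq

    leaf_ids, leaf_seqs, fracs = [], [], []
    for i, leaf in enumerate(leaves):
        s = "".join(BASES[node_seqs[leaf]])
        leaf_ids.append(f"{id_prefix}-{i}")
        leaf_seqs.append(s)
        fracs.append(float((node_seqs[leaf] != seq_idx).mean()))
    return SimulatedEvent(
        annotation=annotation,
        naive_seq=naive_seq,
        n_leaves=n_leaves,
        leaf_ids=leaf_ids,
        leaf_seqs=leaf_seqs,
        raw_seqs=list(leaf_seqs),
        mut_fractions=fracs,
    )


# ---------------------------------------------------------------------------
# somatic indel injection


def apply_indels(work_seq: str, indels) -> str:
    """Re-apply indel records to an indel-free sequence, reconstructing
    the observed read (the inverse of indel reversal)."""
    s = work_seq
    offset = 0
    for ind in sorted(indels, key=lambda x: x.pos):
        p = ind.pos + offset
        if ind.kind == "insertion":
            s = s[:p] + ind.bases + s[p:]
            offset += ind.length
        else:
            s = s[:p] + s[p + ind.length :]
            offset -= ind.length
    return s


def inject_indels(
    event: SimulatedEvent,
    rng: np.random.Generator,
    prob_indel: float = 0.5,
    region: str = "V",
    len_mean: float = 5.0,
) -> SimulatedEvent:
    """Give each leaf, with probability ``prob_indel``, one somatic indel.

    Insertions and deletions are equally likely; lengths are geometric
    with mean ``len_mean``; the position is uniform either on the bulk of
    the V segment (between position 10 and the conserved cysteine) or on
    the CDR3.  Deletions that would run past the region are resampled.
    Truth records are kept per leaf, with positions in the indel-free
    (pre-injection) coordinate frame.
    """
    from .sw import Indel  # local import to avoid a cycle

    if region not in ("V", "CDR3"):
        raise SimulationError(f"indel region must be V or CDR3, not {region!r}")
    ann = event.annotation
    if ann.cdr3_start is None:
        raise SimulationError("annotation lacks CDR3 bounds")
    window = (10, ann.cdr3_start) if region == "V" else (ann.cdr3_start, ann.cdr3_end)
    if window[1] <= window[0]:
        raise SimulationError(f"empty indel window {window}")
    event.indels = {}
    raw = []
    for leaf_id, seq in zip(event.leaf_ids, event.leaf_seqs):
        recs = []
        if rng.random() < prob_indel:
            for _ in range(10_000):
                length = int(rng.geometric(1.0 / len_mean))
                pos = int(rng.integers(window[0], window[1]))
                if rng.random() < 0.5:
                    bases = "".join(rng.choice(BASES, size=length))
                    recs = [Indel(kind="insertion", pos=pos, length=length, bases=bases)]
                    break
                if pos + length <= window[1]:
                    recs = [Indel(kind="deletion", pos=pos, length=length, bases=seq[pos : pos + length])]
                    break
            else:
                raise SimulationError("could not place indel")
        event.indels[leaf_id] = recs
        raw.append(apply_indels(seq, recs))
    event.raw_seqs = raw
    return event


# ---------------------------------------------------------------------------
# whole repertoires


@dataclass
class SimulatedRepertoire:
    """Reads plus complete ground truth for a simulated sample."""

    events: list[SimulatedEvent]
    seed: int

    @property
    def read_ids(self) -> list[str]:
        return [rid for ev in self.events for rid in ev.leaf_ids]

    @property
    def reads(self) -> dict[str, str]:
        return {
            rid: seq
            for ev in self.events
            for rid, seq in zip(ev.leaf_ids, ev.raw_seqs)
        }

    @property
    def true_families(self) -> dict[str, list[str]]:
        return {f"fam{i}": list(ev.leaf_ids) for i, ev in enumerate(self.events)}

    def true_partition(self):
        from .clustering import Partition
        from .hmm import Cluster

        clusters = []
        for ev in self.events:
            ids = tuple(sorted(ev.leaf_ids))
            seq_of = dict(zip(ev.leaf_ids, ev.leaf_seqs))
            clusters.append(
                Cluster(
                    ids=ids,
                    seqs=tuple(seq_of[i] for i in ids),
                    anchor=ev.annotation.cdr3_start,
                    naive_seq=ev.naive_seq,
                    naive_anchor=ev.annotation.cdr3_start,
                )
            )
        return Partition(clusters=clusters)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads.items():
                fh.write(f">{rid}\n{seq}\n")

    def write_truth(self, partition_csv, annotations_tsv, indels_json) -> None:
        with open(partition_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["read_id", "family_id"])
            for fam, ids in self.true_families.items():
                for rid in ids:
                    w.writerow([rid, fam])
        with open(annotations_tsv, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(
                ["family_id", "v_gene", "d_gene", "j_gene", "v_3p_del", "d_5p_del",
                 "d_3p_del", "j_5p_del", "vd_insertion", "dj_insertion", "naive_seq"]
            )
            for i, ev in enumerate(self.events):
                a = ev.annotation
                w.writerow(
                    [f"fam{i}", a.v_gene, a.d_gene, a.j_gene, *a.erosions,
                     a.vd_insertion, a.dj_insertion, a.naive_seq]
                )
        doc = {
            rid: [
                {"kind": ind.kind, "pos": ind.pos, "length": ind.length, "bases": ind.bases}
                for ind in inds
            ]
            for ev in self.events
            for rid, inds in ev.indels.items()
        }
        with open(indels_json, "w") as fh:
            json.dump(doc, fh, indent=1)


def simulate_repertoire(
    params: ParameterSet,
    germline: GermlineSet,
    law: SizeLaw,
    n_seqs: int,
    mut_scale: float = 1.0,
    indel_cfg: dict | None = None,
    seed: int = 0,
) -> SimulatedRepertoire:
    """Generate a full repertoire: family sizes from ``law``, one
    rearrangement per family, mutated leaves, optional indel injection.

    ``mut_scale`` multiplies the per-read mutation-fraction targets drawn
    from the parameter set's empirical distribution (the high-mutation "4x"
    regime uses ``mut_scale=4``).  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    sizes = sample_cluster_sizes(law, n_seqs, rng)
    events = []
    for fam_idx, size in enumerate(sizes):
        naive, ann = sample_rearrangement(params, germline, rng)
        site_rates = _site_rates_for(ann, params, germline)

        def mut_dist(r, _scale=mut_scale):
            arr = params.per_read_mut_dist
            return float(arr[r.integers(arr.size)]) * _scale

        ev = simulate_family(
            naive, ann, size, mut_dist, rng, site_rates=site_rates,
            id_prefix=f"fam{fam_idx}",
        )
        if indel_cfg:
            inject_indels(
                ev,
                rng,
                prob_indel=indel_cfg.get("prob_indel", 0.5),
                region=indel_cfg.get("region", "V"),
                len_mean=indel_cfg.get("len_mean", 5.0),
            )
        events.append(ev)
    return SimulatedRepertoire(events=events, seed=seed)


def _site_rates_for(ann: Annotation, params: ParameterSet, germline: GermlineSet) -> np.ndarray:
    """Relative mutability per naive-sequence position: the parameter
    set's positional rates for germline-encoded sites, 1 for N-region
    sites."""
    v3, d5, d3, j5 = ann.erosions
    parts = [
        np.asarray(params.mut_rates[ann.v_gene])[: len(germline[ann.v_gene].seq) - v3],
        np.ones(len(ann.vd_insertion)) * params.mean_mut,
        np.asarray(params.mut_rates[ann.d_gene])[d5 : len(germline[ann.d_gene].seq) - d3],
        np.ones(len(ann.dj_insertion)) * params.mean_mut,
        np.asarray(params.mut_rates[ann.j_gene])[j5:],
    ]
    rates = np.concatenate(parts)
    return rates / max(rates.mean(), 1e-12)
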