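"""The VDJ multi-HMM: model construction, forward marginals, Viterbi.

The rearrangement process is modelled as a hidden Markov chain with one
state per retained germline position of every candidate V, D and J allele,
plus four non-templated-insertion states (one per nucleotide) at each of
the V-D and D-J junctions.  A path through the chain is an annotated
ancestor hypothesis: it fixes the gene choices, the exonuclease deletion
lengths, the junction insertions, and hence the naive sequence.

Inference runs on an arbitrary number of sequences simultaneously (a
*multi*-HMM): each state emits ``k`` symbols per step, which constrains all
``k`` sequences of a candidate clonal family to a single shared path.  The
forward algorithm then yields the marginal probability ``P(X)`` of a
sequence set ``X`` summed over all annotations, and the quantity driving
agglomerative clustering is the log likelihood ratio

    log P(A ∪ B) − log P(A) − log P(B)

which is positive when common ancestry explains the data better than
separate ancestry.

Everything here works for arbitrary alphabets and state structures (the
container is deliberately generic so small models can be verified against
exhaustive path enumeration); :func:`build_hmm` creates the VDJ-structured
instance from a :class:`~clonalfam.parameters.ParameterSet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .germline import AnchorEroded, GermlineSet, cdr3_bounds

NEG_INF = float("-inf")
#: finite stand-in for log(0) inside matrix products (0 * -inf is nan)
LOG_ZERO = -1e30
_TOL = 1e-9


class HmmError(ValueError):
    pass


@dataclass
class HmmModel:
    """A (multi-)HMM in dense log-space representation.

    ``log_init[s]`` is the probability of starting in state ``s``,
    ``log_trans[s, t]`` of moving from ``s`` to ``t``, and ``log_end[s]``
    of terminating after ``s``; ``log_emit[s, a]`` is the per-symbol
    emission law over ``alphabet``.  The ambiguous symbol emits with
    probability one from every state (it carries no information), which is
    how unequal-length sequences are padded into a common frame.
    """

    state_names: list[str]
    log_init: np.ndarray
    log_trans: np.ndarray
    log_end: np.ndarray
    log_emit: np.ndarray
    alphabet: str = "ACGT"
    ambiguous: str = "N"
    # decoding metadata, present on models built by build_hmm: one entry
    # per state, ("gl", gene, pos) or ("ins", boundary, base)
    state_info: list[tuple] | None = None

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def validate(self) -> "HmmModel":
        S, A = self.n_states, len(self.alphabet)
        if self.log_trans.shape != (S, S) or self.log_emit.shape != (S, A):
            raise HmmError("inconsistent array shapes")
        out = np.exp(self.log_trans).sum(axis=1) + np.exp(self.log_end)
        bad = np.flatnonzero(np.abs(out - 1.0) > 1e-7)
        if bad.size:
            raise HmmError(
                f"outgoing transitions of {self.state_names[bad[0]]} sum to {out[bad[0]]!r}"
            )
        esum = np.exp(self.log_emit).sum(axis=1)
        bad = np.flatnonzero(np.abs(esum - 1.0) > 1e-7)
        if bad.size:
            raise HmmError(
                f"emissions of {self.state_names[bad[0]]} sum to {esum[bad[0]]!r}"
            )
        isum = np.exp(self.log_init).sum()
        if abs(isum - 1.0) > 1e-7:
            raise HmmError(f"initial probabilities sum to {isum!r}")
        return self

    # -- plain-text serialization so models are inspectable and diffable --

    def to_json(self, path=None) -> str:
        def edges(vec_or_row):
            return {
                self.state_names[j]: float(np.exp(v))
                for j, v in enumerate(vec_or_row)
                if v > NEG_INF
            }

        doc = {
            "alphabet": self.alphabet,
            "ambiguous": self.ambiguous,
            "init": edges(self.log_init),
            "states": [
                {
                    "name": self.state_names[i],
                    "emit": [float(np.exp(v)) for v in self.log_emit[i]],
                    "trans": edges(self.log_trans[i]),
                    "end": float(np.exp(self.log_end[i])),
                    "info": list(self.state_info[i]) if self.state_info else None,
                }
                for i in range(self.n_states)
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "HmmModel":
        try:
            doc = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        names = [s["name"] for s in doc["states"]]
        idx = {n: i for i, n in enumerate(names)}
        S, A = len(names), len(doc["alphabet"])
        init = np.zeros(S)
        trans = np.zeros((S, S))
        end = np.zeros(S)
        emit = np.zeros((S, A))
        for name, p in doc["init"].items():
            init[idx[name]] = p
        infos = []
        for i, s in enumerate(doc["states"]):
            emit[i] = s["emit"]
            end[i] = s["end"]
            for name, p in s["trans"].items():
                trans[i, idx[name]] = p
            infos.append(tuple(s["info"]) if s.get("info") else None)
        with np.errstate(divide="ignore"):
            model = cls(
                state_names=names,
                log_init=np.log(init),
                log_trans=np.log(trans),
                log_end=np.log(end),
                log_emit=np.log(emit),
                alphabet=doc["alphabet"],
                ambiguous=doc["ambiguous"],
                state_info=None if all(i is None for i in infos) else infos,
            )
        return model


# ---------------------------------------------------------------------------
# sequence encoding


def _encode(seqs: list[str], model: HmmModel) -> np.ndarray:
    """Symbol-count matrix, shape (L, A); ambiguous symbols contribute 0."""
    if not seqs:
        raise HmmError("need at least one sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise HmmError("multi-HMM sequences must have equal length (pad with N)")
    lut = np.full(128, -2, dtype=np.int8)
    for i, c in enumerate(model.alphabet):
        lut[ord(c)] = i
    lut[ord(model.ambiguous)] = -1
    counts = np.zeros((L, len(model.alphabet)))
    for s in seqs:
        idx = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
        if (idx == -2).any():
            bad = s[int(np.flatnonzero(idx == -2)[0])]
            raise HmmError(f"symbol {bad!r} outside alphabet {model.alphabet}+{model.ambiguous}")
        obs = idx >= 0
        np.add.at(counts, (np.flatnonzero(obs), idx[obs]), 1.0)
    return counts


def _emission_logs(counts: np.ndarray, model: HmmModel) -> np.ndarray:
    """Per-position joint emission log-probabilities, shape (L, S).

    Log-zero entries are clamped to a large negative finite value so the
    matrix product stays nan-free; anything below ``LOG_ZERO / 2`` is an
    impossible emission.
    """
    return counts @ np.maximum(model.log_emit, LOG_ZERO).T


def _strip_flanks(counts: np.ndarray) -> np.ndarray:
    """Drop leading/trailing positions where every sequence is ambiguous.

    Such columns constrain nothing (the ambiguous symbol emits with
    probability one), so ignoring them makes the marginal exactly
    invariant under N-padding.
    """
    observed = np.flatnonzero(counts.sum(axis=1) > 0)
    if observed.size == 0:
        return counts[:0]
    return counts[observed[0] : observed[-1] + 1]


# ---------------------------------------------------------------------------
# forward algorithm


def forward_logprob(seqs: list[str], model: HmmModel) -> float:
    """log P(seqs): marginal probability of jointly emitting all ``k``
    sequences along a single path, summed over all paths.

    Computed with per-position rescaling (mathematically identical to
    log-sum-exp over paths).  Returns ``-inf`` for sequence sets no path
    can generate and ``0.0`` for fully-ambiguous input.
    """
    counts = _strip_flanks(_encode(seqs, model))
    L = counts.shape[0]
    if L == 0:
        return 0.0
    E = _emission_logs(counts, model)
    T = np.exp(model.log_trans)
    acc = 0.0
    m = E[0].max()
    if m < LOG_ZERO / 2:
        return NEG_INF
    a = np.exp(model.log_init) * np.exp(E[0] - m)
    c = a.sum()
    if c == 0.0:
        return NEG_INF
    a /= c
    acc += m + np.log(c)
    for t in range(1, L):
        m = E[t].max()
        if m < LOG_ZERO / 2:
            return NEG_INF
        a = (a @ T) * np.exp(E[t] - m)
        c = a.sum()
        if c == 0.0:
            return NEG_INF
        a /= c
        acc += m + np.log(c)
    z = float(a @ np.exp(model.log_end))
    if z == 0.0:
        return NEG_INF
    return float(acc + np.log(z))


# ---------------------------------------------------------------------------
# Viterbi


def viterbi_path(seqs: list[str], model: HmmModel) -> tuple[list[int], float]:
    """Most probable joint path and its log probability.

    Flanking all-ambiguous positions are ignored exactly as in
    :func:`forward_logprob`, so the returned path covers the observed
    window only.
    """
    counts = _strip_flanks(_encode(seqs, model))
    L = counts.shape[0]
    if L == 0:
        raise HmmError("cannot decode a fully ambiguous sequence set")
    E = _emission_logs(counts, model)
    S = model.n_states
    v = model.log_init + E[0]
    bp = np.zeros((L, S), dtype=np.int32)
    for t in range(1, L):
        M = v[:, None] + model.log_trans
        prev = np.argmax(M, axis=0)
        v = M[prev, np.arange(S)] + E[t]
        bp[t] = prev
    tot = v + model.log_end
    last = int(np.argmax(tot))
    logp = float(tot[last])
    if not np.isfinite(logp) or logp < LOG_ZERO / 2:
        raise HmmError("no path can generate the sequence set")
    path = [0] * L
    path[-1] = last
    for t in range(L - 1, 0, -1):
        path[t - 1] = int(bp[t, path[t]])
    return path, logp


# ---------------------------------------------------------------------------
# VDJ model construction


def _erosion_hazards(dist: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-state (continue, exit) probabilities for a 3' erosion law.

    ``exit[i]`` is the probability of leaving the gene after position
    ``i`` conditional on having reached it; derived from the erosion
    length distribution truncated to the gene length.
    """
    p = np.asarray(dist, dtype=float)[:length]
    if p.sum() <= 0:
        raise HmmError("erosion distribution has no mass within the gene")
    p = p / p.sum()
    p = np.pad(p, (0, length - p.size))
    surv = np.cumsum(p[::-1])[::-1]  # surv[e] = P(erosion >= e)
    exit_p = np.zeros(length)
    for i in range(length):
        e = length - 1 - i  # erosion that ends the gene after position i
        denom = 1.0 - (surv[e + 1] if e + 1 < length else 0.0)  # P(erosion <= e)
        exit_p[i] = p[e] / denom if denom > 0 else 1.0
    return 1.0 - exit_p, exit_p


def _entry_probs(dist: np.ndarray, length: int) -> np.ndarray:
    """5' erosion law truncated to the gene and renormalized: entry at
    state ``i`` means ``i`` bases were deleted from the 5' end."""
    p = np.asarray(dist, dtype=float)[:length]
    if p.sum() <= 0:
        raise HmmError("5' erosion distribution has no mass within the gene")
    p = p / p.sum()
    return np.pad(p, (0, length - p.size))


def build_hmm(params, germline: GermlineSet, candidate_genes: dict[str, list[str]] | None = None) -> HmmModel:
    """Assemble the VDJ multi-HMM over the given candidate genes.

    The state space is restricted to ``candidate_genes`` (default: every
    gene in the germline set), which is how the clustering stage bounds
    the model to the Smith-Waterman matches of the reads involved.

    Structure: the chain enters a V gene (weighted by gene usage) at a
    uniformly-distributed position so that reads truncated on the 5' end
    remain explicable; V positions advance linearly, with exits governed
    by the V 3' erosion law; exits go either straight to a D entry (zero
    junction insertion) or through the four VD N-addition states, whose
    geometric self-transition matches the mean trained insertion length;
    D and J are analogous, and J states terminate with a uniform prior
    over observed 3' endpoints.  Germline states emit their germline base
    with probability ``1 - mut_rate`` at that position, N states emit
    their own base with probability ``1 - mean_mut``.
    """
    params.validate()
    if candidate_genes is None:
        candidate_genes = {r: germline.names(r) for r in ("V", "D", "J")}
    for region in ("V", "D", "J"):
        if not candidate_genes.get(region):
            raise HmmError(f"no candidate {region} genes")

    names: list[str] = []
    info: list[tuple] = []
    gene_span: dict[str, tuple[int, int]] = {}

    def add_gene_states(region):
        for gname in candidate_genes[region]:
            g = germline[gname]
            start = len(names)
            for i in range(len(g.seq)):
                names.append(f"{gname}_{i}")
                info.append(("gl", gname, i))
            gene_span[gname] = (start, len(names))

    def add_insert_states(boundary):
        span = (len(names), len(names) + 4)
        for b in "ACGT":
            names.append(f"insert_{boundary}_{b}")
            info.append(("ins", boundary, b))
        return span

    add_gene_states("V")
    vd_span = add_insert_states("vd")
    add_gene_states("D")
    dj_span = add_insert_states("dj")
    add_gene_states("J")

    S = len(names)
    init = np.zeros(S)
    trans = np.zeros((S, S))
    end = np.zeros(S)
    emit = np.zeros((S, 4))

    # usage renormalized over the candidate restriction
    usage = {}
    for region in ("V", "D", "J"):
        w = np.array([params.gene_usage[region][g] for g in candidate_genes[region]])
        if w.sum() <= 0:
            raise HmmError(f"candidate {region} genes all have zero usage")
        usage[region] = dict(zip(candidate_genes[region], w / w.sum()))

    def entry_vector(region, end_key):
        """Distribution over entry states of a region (usage x 5' erosion)."""
        vec = np.zeros(S)
        for gname in candidate_genes[region]:
            g = germline[gname]
            start, _ = gene_span[gname]
            p5 = _entry_probs(params.erosion_dists[end_key][gname], len(g.seq))
            vec[start : start + len(g.seq)] = usage[region][gname] * p5
        return vec

    def insert_exit(boundary, span, downstream):
        """Junction mass split: direct skip vs entry into N states, and the
        N-state self-transition matched to the conditional mean length."""
        len_dist = np.asarray(params.insertion_len_dists[boundary], dtype=float)
        comp = np.asarray(params.insertion_base_comp[boundary], dtype=float)
        p_zero = len_dist[0]
        p_pos = 1.0 - p_zero
        if p_pos > 0:
            ks = np.arange(len(len_dist))
            m1 = float((ks * len_dist).sum() / p_pos)  # E[len | len >= 1]
            q = max(0.0, 1.0 - 1.0 / max(m1, 1.0))
        else:
            q = 0.0
        lo, hi = span
        # N-state internal structure
        for j, b in enumerate(range(lo, hi)):
            trans[b, lo:hi] += q * comp
            trans[b] += (1.0 - q) * downstream
        exit_vec = np.zeros(S)
        exit_vec[lo:hi] = p_pos * comp
        exit_vec += p_zero * downstream
        return exit_vec

    j_entry = entry_vector("J", "j_5p")
    dj_exit = insert_exit("dj", dj_span, j_entry)
    d_entry = entry_vector("D", "d_5p")
    vd_exit = insert_exit("vd", vd_span, d_entry)

    # V genes: uniform-entry prior, 3' erosion hazards, junction exit
    for gname in candidate_genes["V"]:
        g = germline[gname]
        start, stop = gene_span[gname]
        L = len(g.seq)
        init[start:stop] = usage["V"][gname] / L
        cont, ex = _erosion_hazards(params.erosion_dists["v_3p"][gname], L)
        for i in range(L):
            s = start + i
            if i + 1 < L:
                trans[s, s + 1] = cont[i]
            trans[s] += ex[i] * vd_exit

    # D genes: 3' erosion hazards, junction exit
    for gname in candidate_genes["D"]:
        g = germline[gname]
        start, stop = gene_span[gname]
        L = len(g.seq)
        cont, ex = _erosion_hazards(params.erosion_dists["d_3p"][gname], L)
        for i in range(L):
            s = start + i
            if i + 1 < L:
                trans[s, s + 1] = cont[i]
            trans[s] += ex[i] * dj_exit

    # J genes: uniform exit prior over observed 3' endpoints
    for gname in candidate_genes["J"]:
        g = germline[gname]
        start, stop = gene_span[gname]
        L = len(g.seq)
        for i in range(L):
            s = start + i
            x = 1.0 / (L - i)
            end[s] = x
            if i + 1 < L:
                trans[s, s + 1] = 1.0 - x

    # emissions
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for s, inf in enumerate(info):
        if inf[0] == "gl":
            _, gname, pos = inf
            mu = float(np.asarray(params.mut_rates[gname])[pos])
            row = np.full(4, mu / 3.0)
            row[base_idx[germline[gname].seq[pos]]] = 1.0 - mu
        else:
            _, _, b = inf
            mu = params.mean_mut
            row = np.full(4, mu / 3.0)
            row[base_idx[b]] = 1.0 - mu
        emit[s] = row

    with np.errstate(divide="ignore"):
        model = HmmModel(
            state_names=names,
            log_init=np.log(init),
            log_trans=np.log(trans),
            log_end=np.log(end),
            log_emit=np.log(emit),
            state_info=info,
        )
    return model.validate()


# ---------------------------------------------------------------------------
# annotations


@dataclass
class Annotation:
    """One annotated-ancestor hypothesis: gene calls, erosions, junction
    insertions, the implied naive sequence and its CDR3 bounds."""

    v_gene: str
    d_gene: str
    j_gene: str
    erosions: tuple[int, int, int, int]  # V 3', D 5', D 3', J 5'
    vd_insertion: str
    dj_insertion: str
    naive_seq: str
    cdr3_start: int | None = None
    cdr3_end: int | None = None
    logprob: float = 0.0
    v_5p_trunc: int = 0  # unobserved V 5' positions (read truncation)
    j_3p_trunc: int = 0

    @property
    def cdr3_length(self) -> int | None:
        if self.cdr3_start is None:
            return None
        return self.cdr3_end - self.cdr3_start


def decode_path(path: list[int], model: HmmModel, germline: GermlineSet, logprob: float = 0.0) -> Annotation:
    """Translate a state path into an :class:`Annotation`."""
    if model.state_info is None:
        raise HmmError("model carries no decoding metadata")
    infos = [model.state_info[s] for s in path]
    naive = []
    regions: dict[str, list[tuple[int, int]]] = {"V": [], "D": [], "J": []}
    inserts = {"vd": [], "dj": []}
    for t, inf in enumerate(infos):
        if inf[0] == "gl":
            _, gname, pos = inf
            naive.append(germline[gname].seq[pos])
            regions[germline[gname].region].append((t, pos))
        else:
            _, boundary, b = inf
            naive.append(b)
            inserts[boundary].append(b)
    for r in ("V", "D", "J"):
        if not regions[r]:
            raise HmmError(f"path contains no {r} states")

    def gene_of(r):
        t0, _ = regions[r][0]
        return infos[t0][1]

    v_gene, d_gene, j_gene = gene_of("V"), gene_of("D"), gene_of("J")
    v_first, v_last = regions["V"][0][1], regions["V"][-1][1]
    d_first, d_last = regions["D"][0][1], regions["D"][-1][1]
    j_first, j_last = regions["J"][0][1], regions["J"][-1][1]
    erosions = (
        len(germline[v_gene].seq) - 1 - v_last,
        d_first,
        len(germline[d_gene].seq) - 1 - d_last,
        j_first,
    )
    ann = Annotation(
        v_gene=v_gene,
        d_gene=d_gene,
        j_gene=j_gene,
        erosions=erosions,
        vd_insertion="".join(inserts["vd"]),
        dj_insertion="".join(inserts["dj"]),
        naive_seq="".join(naive),
        logprob=logprob,
        v_5p_trunc=v_first,
        j_3p_trunc=len(germline[j_gene].seq) - 1 - j_last,
    )
    try:
        start, stop = cdr3_bounds(ann, germline)
        ann.cdr3_start = start - ann.v_5p_trunc
        ann.cdr3_end = stop - ann.v_5p_trunc
        if ann.cdr3_start < 0 or ann.cdr3_end > len(ann.naive_seq):
            ann.cdr3_start = ann.cdr3_end = None
    except AnchorEroded:
        pass
    return ann


def viterbi_annotate(seqs: list[str], model: HmmModel, germline: GermlineSet) -> Annotation:
    """Joint Viterbi annotation of ``k`` sequences: the single most
    probable annotated ancestor shared by the whole set."""
    path, logp = viterbi_path(seqs, model)
    return decode_path(path, model, germline, logprob=logp)


# ---------------------------------------------------------------------------
# clusters and likelihood ratios


@dataclass
class Cluster:
    """A candidate clonal family: read ids, their working sequences in a
    common coordinate frame, and cached inference results."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    anchor: int | None = None  # conserved-cysteine position in seq coordinates
    log_marginal: float | None = None
    naive_seq: str | None = None
    naive_anchor: int | None = None

    def __post_init__(self) -> None:
        if not self.ids:
            raise HmmError("empty cluster")
        if len(set(self.ids)) != len(self.ids):
            raise HmmError("duplicate ids in cluster")
        if tuple(sorted(self.ids)) != tuple(self.ids):
            order = np.argsort(np.array(self.ids, dtype=object))
            self.ids = tuple(self.ids[i] for i in order)
            self.seqs = tuple(self.seqs[i] for i in order)

    def __len__(self) -> int:
        return len(self.ids)


def pad_union_seqs(a: Cluster, b: Cluster) -> tuple[tuple[str, ...], int]:
    """Place two clusters' sequences in a common frame by aligning their
    conserved-cysteine anchors and N-padding both ends."""
    anc_a = a.anchor if a.anchor is not None else 0
    anc_b = b.anchor if b.anchor is not None else 0
    anc = max(anc_a, anc_b)
    seqs = ["N" * (anc - anc_a) + s for s in a.seqs] + [
        "N" * (anc - anc_b) + s for s in b.seqs
    ]
    L = max(len(s) for s in seqs)
    return tuple(s + "N" * (L - len(s)) for s in seqs), anc


def cluster_log_marginal(cluster: Cluster, model: HmmModel) -> float:
    """Forward marginal of a cluster, cached on the cluster object."""
    if cluster.log_marginal is None:
        cluster.log_marginal = forward_logprob(list(cluster.seqs), model)
    return cluster.log_marginal


def log_likelihood_ratio(a: Cluster, b: Cluster, model: HmmModel, cache: dict | None = None) -> float:
    """log P(A ∪ B) − log P(A) − log P(B) under the multi-HMM.

    Positive values favour the hypothesis that both clusters descend from
    one rearrangement event.  Cached single-cluster marginals are reused;
    the union marginal is stored in ``cache`` keyed by the sorted id tuple.
    """
    if set(a.ids) & set(b.ids):
        raise HmmError("clusters overlap")
    la = cluster_log_marginal(a, model)
    lb = cluster_log_marginal(b, model)
    key = tuple(sorted(a.ids + b.ids))
    if cache is not None and key in cache:
        lab = cache[key]
    else:
        seqs, _ = pad_union_seqs(a, b)
        lab = forward_logprob(list(seqs), model)
        if cache is not None:
            cache[key] = lab
    return lab - la - lb


def partition_logprob(partition, model: HmmModel) -> float:
    """Total log probability of a partition: the sum of its clusters'
    forward marginals (clusters are independent rearrangement events)."""
    total = 0.0
    for cluster in partition.clusters:
        total += cluster_log_marginal(cluster, model)
    return total
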