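"""Preliminary Smith-Waterman annotation, indel reversal, and training.

Before any HMM work, every read is annotated by local alignment against
the germline genes: best V first, then J in the remaining 3' portion, then
D in between.  This stage has three jobs:

1. produce candidate gene lists per region (everything scoring within a
   margin of the best), which bound the HMM state space downstream;
2. detect and "reverse" somatic insertion/deletion mutations inside
   germline-encoded segments -- inserted bases are excised and deleted
   germline bases restored, so the rest of the pipeline sees indel-free
   sequences while the original read is kept reconstructable;
3. provide the cycle-0 annotations for Viterbi training of the HMM
   parameters.

Low-mutation reads can fail to find a D segment at the default 5:1
match:mismatch scores; such reads are retried at 5:2 and then 5:3 (the
retry ladder).  The gap-opening penalty defaults to 30, which tunes
sensitivity to indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align, SeqIO

from .germline import GermlineSet
from .parameters import (
    BOUNDARIES,
    EROSION_ENDS,
    EROSION_REGION,
    ParameterSet,
)

AMBIG = "N"


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SwScores:
    """Smith-Waterman scoring; penalties are positive by convention.

    The gap-opening penalty of 30 controls indel sensitivity; the small
    extension penalty makes a multi-base indel cost essentially one
    opening event, matching the view of somatic indels as single events
    of geometric length.
    """

    match: int = 5
    mismatch: int = 1
    gap_open: int = 30
    gap_extend: int = 3

    def __post_init__(self) -> None:
        if min(self.match, self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("all scores/penalties must be strictly positive")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = -self.mismatch
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        return a


@dataclass(frozen=True)
class Indel:
    """One reversed (or injected) indel.

    ``pos`` is 0-based in the corrected (indel-free) frame; ``bases`` are
    the excised read bases for an insertion, or the restored germline
    bases for a deletion.  Applying the record to the corrected sequence
    reconstructs the observed read.
    """

    kind: str  # insertion | deletion
    pos: int
    length: int
    bases: str

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length < 1 or self.length != len(self.bases):
            raise ValueError("indel length must be >= 1 and match bases")


@dataclass
class SequenceRecord:
    """One read: the observed sequence, the indel-reversed working
    sequence used by all downstream stages, and the reversal records."""

    id: str
    raw_seq: str
    work_seq: str = ""
    indels: list[Indel] = field(default_factory=list)
    sw: "SwAnnotation | None" = None

    def __post_init__(self) -> None:
        self.raw_seq = self.raw_seq.upper()
        if not self.work_seq:
            self.work_seq = self.raw_seq
        else:
            self.work_seq = self.work_seq.upper()


def read_sequences(path, fmt: str | None = None) -> list[SequenceRecord]:
    """Load reads from FASTA/FASTQ (format inferred from the suffix)."""
    if fmt is None:
        fmt = "fastq" if str(path).lower().endswith(("fq", "fastq")) else "fasta"
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


@dataclass
class RegionMatch:
    """Best alignment of one region: gene, score, intervals (read and
    germline, 0-based half-open) and the aligned block structure."""

    gene: str
    score: float
    read_start: int
    read_end: int
    gl_start: int
    gl_end: int
    # parallel lists of (read block, germline block), absolute read coords
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    gl_seq: str = ""  # the matched gene's sequence (for deletion reversal)

    @property
    def has_gaps(self) -> bool:
        return len(self.blocks) > 1

    def read_pos_of(self, gl_pos: int) -> int | None:
        """Map a germline position through the alignment, or None if it
        falls in a gap or outside the aligned span."""
        for (rs, re_), (gs, ge) in self.blocks:
            if gs <= gl_pos < ge:
                return rs + (gl_pos - gs)
        return None


@dataclass
class SwAnnotation:
    """Smith-Waterman annotation of one read."""

    regions: dict[str, RegionMatch] = field(default_factory=dict)
    candidates: dict[str, list[str]] = field(default_factory=dict)
    n_mutations: int = 0
    aligned_length: int = 0
    mut_fraction: float = 0.0
    failed: str | None = None
    ladder: list[tuple[int, int]] = field(default_factory=list)
    v_anchor_read: int | None = None
    j_anchor_read: int | None = None

    @property
    def ok(self) -> bool:
        return self.failed is None

    def erosions(self, germline: GermlineSet) -> tuple[int, int, int, int]:
        """Erosion estimates implied by the local-alignment endpoints."""
        v, d, j = (self.regions[r] for r in "VDJ")
        return (
            len(germline[v.gene].seq) - v.gl_end,
            d.gl_start,
            len(germline[d.gene].seq) - d.gl_end,
            j.gl_start,
        )

    def insertions(self, read_seq: str) -> tuple[str, str]:
        v, d, j = (self.regions[r] for r in "VDJ")
        vd = read_seq[v.read_end : d.read_start] if d.read_start >= v.read_end else ""
        dj = read_seq[d.read_end : j.read_start] if j.read_start >= d.read_end else ""
        return vd, dj


def _failed(reason: str, ladder) -> SwAnnotation:
    return SwAnnotation(failed=reason, ladder=list(ladder))


def _align_region(seq, genes, aligner, offset, margin=0.8):
    """Score every gene against a read window; return (best RegionMatch,
    candidate names).  Ties break toward the earlier gene in the set."""
    scored = []
    for g in genes:
        if len(seq) < 1:
            continue
        s = aligner.score(seq, g.seq)
        scored.append((s, g))
    if not scored:
        return None, []
    best_score = max(s for s, _ in scored)
    if best_score <= 0:
        return None, []
    best_gene = next(g for s, g in scored if s == best_score)
    candidates = [g.name for s, g in scored if s >= margin * best_score]
    aln = aligner.align(seq, best_gene.seq)[0]
    read_blocks, gl_blocks = aln.aligned
    blocks = [
        ((int(rs) + offset, int(re_) + offset), (int(gs), int(ge)))
        for (rs, re_), (gs, ge) in zip(read_blocks, gl_blocks)
    ]
    match = RegionMatch(
        gene=best_gene.name,
        score=float(best_score),
        read_start=blocks[0][0][0],
        read_end=blocks[-1][0][1],
        gl_start=blocks[0][1][0],
        gl_end=blocks[-1][1][1],
        blocks=blocks,
        gl_seq=best_gene.seq,
    )
    return match, candidates


def sw_align_read(
    record: SequenceRecord,
    germline: GermlineSet,
    scores: SwScores = SwScores(),
    min_length: int = 50,
    candidate_margin: float = 0.8,
    min_v_score: int | None = None,
    min_j_score: int | None = None,
    min_d_score: int | None = None,
) -> SwAnnotation:
    """Annotate one read by per-region local alignment.

    V is located first on the whole read, then J on the remaining 3'
    portion, then D between them.  Region score floors (defaults scaled
    from the match score) decide when a read is unannotatable or has no
    D match; candidate lists keep every gene within ``candidate_margin``
    of the best per-region score.
    """
    seq = record.work_seq
    ladder = [(scores.match, scores.mismatch)]
    if len(seq) < min_length:
        return _failed(f"read shorter than {min_length} nt", ladder)
    if min_v_score is None:
        min_v_score = 20 * scores.match
    if min_j_score is None:
        min_j_score = 8 * scores.match
    if min_d_score is None:
        min_d_score = 5 * scores.match  # "no D match" floor
    aligner = scores.aligner()

    v_match, v_cands = _align_region(seq, germline.region_genes("V"), aligner, 0, candidate_margin)
    if v_match is None or v_match.score < min_v_score:
        return _failed("no V alignment above the minimal score", ladder)
    j_match, j_cands = _align_region(
        seq[v_match.read_end :], germline.region_genes("J"), aligner, v_match.read_end, candidate_margin
    )
    if j_match is None or j_match.score < min_j_score:
        return _failed("no J alignment above the minimal score", ladder)
    d_window = seq[v_match.read_end : j_match.read_start]
    d_match, d_cands = _align_region(
        d_window, germline.region_genes("D"), aligner, v_match.read_end, candidate_margin
    )
    if d_match is not None and d_match.score < min_d_score:
        d_match, d_cands = None, []

    ann = SwAnnotation(
        regions={"V": v_match, "J": j_match} | ({"D": d_match} if d_match else {}),
        candidates={"V": v_cands, "J": j_cands, "D": d_cands},
        ladder=ladder,
    )
    n_mut = 0
    n_aln = 0
    for match in ann.regions.values():
        gseq = germline[match.gene].seq
        for (rs, re_), (gs, ge) in match.blocks:
            for rp, gp in zip(range(rs, re_), range(gs, ge)):
                if seq[rp] == AMBIG:
                    continue
                n_aln += 1
                n_mut += seq[rp] != gseq[gp]
    ann.n_mutations = n_mut
    ann.aligned_length = n_aln
    ann.mut_fraction = n_mut / n_aln if n_aln else 0.0
    ann.v_anchor_read = v_match.read_pos_of(germline[v_match.gene].anchor)
    ann.j_anchor_read = j_match.read_pos_of(germline[j_match.gene].anchor)
    return ann


def retry_ladder(
    record: SequenceRecord,
    germline: GermlineSet,
    scores: SwScores = SwScores(),
    **kwargs,
) -> SwAnnotation:
    """The match:mismatch retry ladder: 5:1, then 5:2, then 5:3.

    Low-mutation reads can come back without a D match at 5:1 (the high
    match:mismatch ratio lets spurious V/J extension swallow the short D);
    increasing the mismatch penalty recovers them.  The first annotation
    with a D match wins; otherwise the last rung's result is returned.
    """
    rungs = [1, 2, 3]
    tried = []
    ann = None
    for mm in rungs:
        rung_scores = replace(scores, mismatch=mm * scores.mismatch)
        ann = sw_align_read(record, germline, rung_scores, **kwargs)
        tried.append((rung_scores.match, rung_scores.mismatch))
        if ann.ok and "D" in ann.regions:
            break
    ann.ladder = tried
    return ann


def reverse_indels(record: SequenceRecord, annotation: SwAnnotation) -> SequenceRecord:
    """Excise inferred insertions and restore inferred deletions.

    Every gap inside an aligned germline segment becomes an
    :class:`Indel` record; junction (N-region) bases are untouched.  The
    returned record's ``work_seq`` is the corrected sequence and
    re-applying the records reconstructs ``raw_seq`` exactly.
    """
    if record.indels:
        raise ValueError(f"{record.id}: indels already reversed")
    if not annotation.ok:
        return record
    seq = record.work_seq
    # edits in read coordinates: (read_pos, kind, length, germline bases)
    edits: list[tuple[int, str, int, str]] = []
    for match in annotation.regions.values():
        for prev, nxt in zip(match.blocks, match.blocks[1:]):
            (_, pre), (_, pge) = prev
            (nrs, _), (ngs, _) = nxt
            dq, dg = nrs - pre, ngs - pge
            if dq > 0:  # extra read bases: somatic insertion
                edits.append((pre, "insertion", dq, ""))
            if dg > 0:  # missing read bases: somatic deletion
                edits.append((pre + max(dq, 0), "deletion", dg, match.gl_seq[pge:ngs]))
    if not edits:
        return record
    edits.sort()
    out: list[str] = []
    cur = 0
    indels: list[Indel] = []
    for pos, kind, length, bases in edits:
        out.append(seq[cur:pos])
        at = sum(len(x) for x in out)
        if kind == "insertion":
            indels.append(Indel("insertion", at, length, seq[pos : pos + length]))
            cur = pos + length
        else:
            out.append(bases)
            indels.append(Indel("deletion", at, length, bases))
            cur = pos
    out.append(seq[cur:])
    work = "".join(out)
    from .simulate import apply_indels

    assert apply_indels(work, indels) == seq, "indel reversal round-trip failed"
    return SequenceRecord(record.id, record.raw_seq, work, indels)


def annotate_reads(
    records: list[SequenceRecord],
    germline: GermlineSet,
    scores: SwScores = SwScores(),
    reverse: bool = True,
    **kwargs,
) -> list[SequenceRecord]:
    """Full preliminary stage: retry-ladder annotation, optional indel
    reversal (with re-annotation of corrected reads), results attached to
    each record's ``.sw``.  Unannotatable reads keep ``sw.failed``."""
    out = []
    for rec in records:
        ann = retry_ladder(rec, germline, scores, **kwargs)
        if reverse and ann.ok and any(m.has_gaps for m in ann.regions.values()):
            rec = reverse_indels(rec, ann)
            ann = retry_ladder(rec, germline, scores, **kwargs)
        rec.sw = ann
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# parameter estimation (Viterbi training)


def _empty_counts(germline: GermlineSet):
    return {
        "usage": {r: {g.name: 0 for g in germline.region_genes(r)} for r in "VDJ"},
        "erosions": {end: {g.name: [] for g in germline.region_genes(EROSION_REGION[end])} for end in EROSION_ENDS},
        "ins_len": {b: [] for b in BOUNDARIES},
        "ins_bases": {b: [] for b in BOUNDARIES},
        "cover": {g: np.zeros(len(germline[g].seq)) for g in germline.names()},
        "mut": {g: np.zeros(len(germline[g].seq)) for g in germline.names()},
        "read_fracs": [],
    }


def _hist(values, support: int, pseudo: float = 0.05) -> np.ndarray:
    h = np.full(support, pseudo)
    for v in values:
        if 0 <= v < support:
            h[v] += 1.0
    return h / h.sum()


def _counts_to_params(counts, germline: GermlineSet, floor: int) -> ParameterSet:
    usage = {}
    for region in "VDJ":
        c = counts["usage"][region]
        total = sum(c.values())
        usage[region] = {g: (n / total if total else 1.0 / len(c)) for g, n in c.items()}

    erosion_dists = {}
    for end in EROSION_ENDS:
        per_gene = {}
        pooled = [v for vals in counts["erosions"][end].values() for v in vals]
        for gname, vals in counts["erosions"][end].items():
            L = len(germline[gname].seq)
            support = min(L, max(pooled, default=0) + 3)
            use = vals if len(vals) >= floor else pooled
            per_gene[gname] = _hist(use, max(support, 1))
        erosion_dists[end] = per_gene

    insertion_len_dists = {}
    insertion_base_comp = {}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for b in BOUNDARIES:
        lens = counts["ins_len"][b]
        insertion_len_dists[b] = _hist(lens, max(lens, default=0) + 3)
        comp = np.ones(4)  # +1 smoothing
        for base in counts["ins_bases"][b]:
            if base in base_idx:
                comp[base_idx[base]] += 1
        insertion_base_comp[b] = comp / comp.sum()

    mut_rates = {}
    region_rates = {}
    for region in "VDJ":
        cov = np.concatenate([counts["cover"][g.name] for g in germline.region_genes(region)])
        mut = np.concatenate([counts["mut"][g.name] for g in germline.region_genes(region)])
        region_rates[region] = float(mut.sum() / cov.sum()) if cov.sum() else 0.0
    for region in "VDJ":
        for g in germline.region_genes(region):
            cov, mut = counts["cover"][g.name], counts["mut"][g.name]
            if counts["usage"][region][g.name] >= floor:
                with np.errstate(invalid="ignore"):
                    rates = np.where(cov > 0, mut / np.maximum(cov, 1), region_rates[region])
            else:
                rates = np.full(len(g.seq), region_rates[region])
            mut_rates[g.name] = np.clip(rates, 0.0, 1.0)

    fracs = np.asarray(counts["read_fracs"], dtype=float)
    return ParameterSet(
        gene_usage=usage,
        erosion_dists=erosion_dists,
        insertion_len_dists=insertion_len_dists,
        insertion_base_comp=insertion_base_comp,
        mut_rates=mut_rates,
        mean_mut=float(fracs.mean()) if fracs.size else 0.0,
        per_read_mut_dist=fracs if fracs.size else np.zeros(1),
    ).validate()


def _tally_sw(counts, rec: SequenceRecord, germline: GermlineSet) -> None:
    ann = rec.sw
    for region, match in ann.regions.items():
        counts["usage"][region][match.gene] += 1
        gseq = germline[match.gene].seq
        for (rs, re_), (gs, ge) in match.blocks:
            for rp, gp in zip(range(rs, re_), range(gs, ge)):
                if rec.work_seq[rp] == AMBIG:
                    continue
                counts["cover"][match.gene][gp] += 1
                counts["mut"][match.gene][gp] += rec.work_seq[rp] != gseq[gp]
    if len(ann.regions) == 3:
        v3, d5, d3, j5 = ann.erosions(germline)
        for end, val in zip(EROSION_ENDS, (v3, d5, d3, j5)):
            region = EROSION_REGION[end]
            counts["erosions"][end][ann.regions[region].gene].append(val)
        vd, dj = ann.insertions(rec.work_seq)
        for b, ins in zip(BOUNDARIES, (vd, dj)):
            counts["ins_len"][b].append(len(ins))
            counts["ins_bases"][b].extend(ins)
    counts["read_fracs"].append(ann.mut_fraction)


def _tally_hmm(counts, rec: SequenceRecord, annotation, germline: GermlineSet) -> None:
    a = annotation
    counts["usage"]["V"][a.v_gene] += 1
    counts["usage"]["D"][a.d_gene] += 1
    counts["usage"]["J"][a.j_gene] += 1
    v3, d5, d3, j5 = a.erosions
    for end, val in zip(EROSION_ENDS, (v3, d5, d3, j5)):
        gene = {"V": a.v_gene, "D": a.d_gene, "J": a.j_gene}[EROSION_REGION[end]]
        counts["erosions"][end][gene].append(val)
    counts["ins_len"]["vd"].append(len(a.vd_insertion))
    counts["ins_bases"]["vd"].extend(a.vd_insertion)
    counts["ins_len"]["dj"].append(len(a.dj_insertion))
    counts["ins_bases"]["dj"].extend(a.dj_insertion)
    # per-position mutation counts: walk the naive-sequence layout
    layout = []
    layout += [(a.v_gene, i) for i in range(a.v_5p_trunc, len(germline[a.v_gene].seq) - v3)]
    layout += [None] * len(a.vd_insertion)
    layout += [(a.d_gene, i) for i in range(d5, len(germline[a.d_gene].seq) - d3)]
    layout += [None] * len(a.dj_insertion)
    layout += [(a.j_gene, i) for i in range(j5, len(germline[a.j_gene].seq) - a.j_3p_trunc)]
    n_mut = n_cov = 0
    for pos, slot in enumerate(layout):
        if pos >= len(rec.work_seq):
            break
        obs = rec.work_seq[pos]
        if obs == AMBIG:
            continue
        if slot is not None:
            gene, gp = slot
            counts["cover"][gene][gp] += 1
            diff = obs != a.naive_seq[pos]
            counts["mut"][gene][gp] += diff
            n_cov += 1
            n_mut += diff
    counts["read_fracs"].append(n_mut / n_cov if n_cov else 0.0)


def viterbi_train(
    records: list[SequenceRecord],
    germline: GermlineSet,
    n_cycles: int = 1,
    scores: SwScores = SwScores(),
    min_reads: int = 50,
    floor: int = 20,
) -> ParameterSet:
    """Estimate rearrangement parameters from a sample of reads.

    Cycle 0 estimates everything from the Smith-Waterman annotations;
    each further cycle re-annotates every read with the Viterbi algorithm
    under the HMM built from the current estimate and re-estimates.
    Genes observed fewer than ``floor`` times fall back to region-pooled
    distributions.
    """
    if n_cycles < 1:
        raise TrainingError("n_cycles must be >= 1")
    if any(r.sw is None for r in records):
        records = annotate_reads(records, germline, scores)
    usable = [r for r in records if r.sw.ok]
    if len(usable) < min_reads:
        raise TrainingError(
            f"only {len(usable)} annotatable reads; training requires at least {min_reads}"
        )
    counts = _empty_counts(germline)
    for rec in usable:
        _tally_sw(counts, rec, germline)
    params = _counts_to_params(counts, germline, floor)

    for _ in range(n_cycles - 1):
        from .hmm import build_hmm, viterbi_annotate

        cands = {
            r: [g for g, p in params.gene_usage[r].items() if p > 0] for r in "VDJ"
        }
        model = build_hmm(params, germline, cands)
        counts = _empty_counts(germline)
        for rec in usable:
            try:
                ann = viterbi_annotate([rec.work_seq], model, germline)
            except Exception:
                continue
            _tally_hmm(counts, rec, ann, germline)
        params = _counts_to_params(counts, germline, floor)
    return params
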