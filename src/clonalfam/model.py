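"""High-level modelling interface.

:class:`ClonalFamilyModel` bundles the whole inference pipeline behind a
fit-style API: construct it from reads plus a germline set, call
:meth:`~ClonalFamilyModel.fit`, and receive a :class:`PartitionResults`
carrying the inferred partition, its likelihood trajectory, per-cluster
naive sequences and a printable summary.

    >>> model = ClonalFamilyModel.from_fasta("reads.fasta", germline)
    >>> res = model.fit(mode="full")
    >>> print(res.summary())

The lower-level modules (:mod:`~clonalfam.sw`, :mod:`~clonalfam.hmm`,
:mod:`~clonalfam.clustering`, ...) remain usable on their own; this class
only orchestrates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import clustering as _cl
from . import sw as _sw
from .germline import GermlineSet
from .hmm import Cluster
from .parameters import ParameterSet


class FitError(RuntimeError):
    pass


class ClonalFamilyModel:
    """Clonal family inference model for one heavy-chain sample.

    Parameters
    ----------
    records : list of SequenceRecord
        The reads.  Strings are accepted via :meth:`from_sequences`.
    germline : GermlineSet
        Germline genes with conserved-codon anchors.
    params : ParameterSet, optional
        Rearrangement parameters.  When omitted they are trained on the
        sample itself (a cycle of Viterbi training seeded by the
        Smith-Waterman annotations).
    thresholds : ThresholdConfig, optional
    scores : SwScores, optional
    n_workers : int
        Worker threads for pair-likelihood evaluation (results are
        independent of this number).
    """

    def __init__(
        self,
        records,
        germline: GermlineSet,
        params: ParameterSet | None = None,
        thresholds: _cl.ThresholdConfig | None = None,
        scores: _sw.SwScores | None = None,
        n_workers: int = 1,
        train_cycles: int = 1,
        train_min_reads: int = 50,
    ):
        self.records = list(records)
        self.germline = germline
        self.params = params
        self.thresholds = thresholds or _cl.ThresholdConfig()
        self.scores = scores or _sw.SwScores()
        self.n_workers = n_workers
        self.train_cycles = train_cycles
        self.train_min_reads = train_min_reads
        self._annotated = False

    @classmethod
    def from_fasta(cls, path, germline: GermlineSet, **kwargs) -> "ClonalFamilyModel":
        return cls(_sw.read_sequences(path), germline, **kwargs)

    @classmethod
    def from_sequences(cls, seqs: dict, germline: GermlineSet, **kwargs) -> "ClonalFamilyModel":
        recs = [_sw.SequenceRecord(rid, s) for rid, s in seqs.items()]
        return cls(recs, germline, **kwargs)

    # -- pipeline stages -------------------------------------------------

    def annotate(self) -> "ClonalFamilyModel":
        """Smith-Waterman stage: retry-ladder annotation and indel
        reversal for every read (idempotent)."""
        if not self._annotated:
            self.records = _sw.annotate_reads(self.records, self.germline, self.scores)
            self._annotated = True
        return self

    @property
    def annotatable(self) -> list:
        self.annotate()
        return [r for r in self.records if r.sw.ok]

    @property
    def failed_reads(self) -> dict[str, str]:
        self.annotate()
        return {r.id: r.sw.failed for r in self.records if not r.sw.ok}

    def train(self) -> ParameterSet:
        """Estimate rearrangement parameters from the sample (cached)."""
        if self.params is None:
            self.annotate()
            self.params = _sw.viterbi_train(
                self.records,
                self.germline,
                n_cycles=self.train_cycles,
                scores=self.scores,
                min_reads=self.train_min_reads,
            )
        return self.params

    def fit(self, mode: str = "full", seed_id: str | None = None) -> "PartitionResults":
        """Infer the clonal family partition.

        mode is one of ``full`` (likelihood-ratio agglomeration),
        ``point`` (joint naive-sequence distance), ``greedy``
        (single-read naive centroid clustering) or ``seed`` (reconstruct
        only the family containing ``seed_id``).
        """
        self.annotate()
        params = self.train()
        usable = self.annotatable
        if not usable:
            raise FitError("no annotatable reads")
        sample_mut = _cl.sample_mutation_level(usable)
        trajectory: list[_cl.Partition] = []
        seed_cluster: Cluster | None = None
        if mode == "full":
            trajectory = _cl.agglomerate_full(
                usable, thresholds=self.thresholds, germline=self.germline,
                params=params, n_workers=self.n_workers,
            )
            partition = trajectory[-1]
        elif mode == "point":
            partition = _cl.point_partition(
                usable, thresholds=self.thresholds, germline=self.germline, params=params
            )
        elif mode == "greedy":
            partition = _cl.greedy_partition(
                usable, thresholds=self.thresholds, germline=self.germline, params=params
            )
        elif mode == "seed":
            if seed_id is None:
                raise FitError("seed mode requires seed_id")
            seed_cluster = _cl.seeded_partition(
                usable, seed_id, thresholds=self.thresholds, germline=self.germline,
                params=params, n_workers=self.n_workers,
            )
            rest = [
                Cluster(ids=(r.id,), seqs=(r.work_seq,))
                for r in usable
                if r.id not in seed_cluster.ids
            ]
            partition = _cl.Partition(clusters=[seed_cluster] + rest)
        else:
            raise FitError(f"unknown mode {mode!r}")
        return PartitionResults(
            model=self,
            mode=mode,
            partition=partition,
            trajectory=trajectory,
            seed_cluster=seed_cluster,
            sample_mutation=sample_mut,
        )


@dataclass
class PartitionResults:
    """Results of a clonal family fit."""

    model: ClonalFamilyModel
    mode: str
    partition: _cl.Partition
    trajectory: list = field(default_factory=list)
    seed_cluster: Cluster | None = None
    sample_mutation: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(self.partition)

    @property
    def cluster_sizes(self) -> list[int]:
        return sorted((len(c) for c in self.partition.clusters), reverse=True)

    @property
    def total_logprob(self) -> float | None:
        return self.partition.total_logprob

    def naive_sequences(self) -> dict[tuple, str | None]:
        return {c.ids: c.naive_seq for c in self.partition.clusters}

    def evaluate(self, truth: _cl.Partition):
        from .evaluate import per_read_metrics

        return per_read_metrics(truth, self.partition)

    def to_dataframe(self):
        return self.partition.to_dataframe()

    def write_csv(self, path) -> None:
        self.partition.write_csv(path)

    def write_trajectory(self, path) -> None:
        import json

        doc = [
            {
                "n_clusters": len(p),
                "total_logprob": p.total_logprob,
                "merge": p.merge_info,
                "clusters": [list(c.ids) for c in p.clusters],
            }
            for p in self.trajectory
        ]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def plot_cluster_sizes(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sizes = self.cluster_sizes
        vals, counts = np.unique(sizes, return_counts=True)
        ax.scatter(vals, counts)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("cluster size")
        ax.set_ylabel("number of clusters")
        return ax

    def summary(self) -> str:
        n_reads = sum(len(c) for c in self.partition.clusters)
        sizes = self.cluster_sizes
        lines = [
            "Clonal family inference results",
            "=" * 46,
            f"{'mode':<28}{self.mode:>18}",
            f"{'reads clustered':<28}{n_reads:>18}",
            f"{'unannotatable reads':<28}{len(self.model.failed_reads):>18}",
            f"{'sample mutation fraction':<28}{self.sample_mutation:>18.4f}",
            f"{'clusters':<28}{self.n_clusters:>18}",
            f"{'largest cluster':<28}{sizes[0]:>18}",
            f"{'singletons':<28}{sum(1 for s in sizes if s == 1):>18}",
        ]
        if self.total_logprob is not None:
            lines.append(f"{'partition log probability':<28}{self.total_logprob:>18.2f}")
        if self.trajectory:
            lines.append(f"{'agglomeration steps':<28}{len(self.trajectory) - 1:>18}")
        if self.seed_cluster is not None:
            lines.append(f"{'seed family size':<28}{len(self.seed_cluster):>18}")
        lines.append("=" * 46)
        return "\n".join(lines)
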