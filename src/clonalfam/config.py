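"""Run configuration: one serializable object holding every knob.

Defaults reproduce the method's standard constants: naive-Hamming gates
0.015 (low, any mutation level) and 0.08 -> 0.15 (high, at 5% -> 20%
sample mutation), point-mode thresholds 0.035 -> 0.06, the likelihood
ratio threshold table {2: 18, 3: 16, 4: 15, 5: 14, >=6: 13}, and the
Smith-Waterman 5:1 match:mismatch ladder with gap-opening penalty 30.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .clustering import LLR_TABLE, ThresholdConfig
from .simulate import SizeLaw
from .sw import SwScores


@dataclass
class RunConfig:
    """Configuration for a pipeline run (any subcommand)."""

    # what to run
    mode: str = "full"  # full | point | greedy | seed
    seed_id: str | None = None

    # inputs (None for the packaged synthetic germline set)
    reads: str | None = None
    v_genes: str | None = None
    d_genes: str | None = None
    j_genes: str | None = None
    anchors: str | None = None

    # Smith-Waterman
    match: int = 5
    mismatch: int = 1
    gap_open: int = 30
    gap_extend: int = 3
    min_read_length: int = 50

    # clustering thresholds (None = dynamic, mutation-dependent)
    lo_hf: float = 0.015
    hi_hf: float | None = None
    point_hf: float | None = None
    greedy_id: float | None = None
    llr_table: dict[int, float] = field(default_factory=lambda: dict(LLR_TABLE))

    # training
    train_cycles: int = 1
    train_min_reads: int = 50

    # simulation
    n_seqs: int = 1000
    size_law: str = "geometric"
    size_mean: float = 10.0
    zipf_exponent: float = 2.3
    zipf_max: int = 1000
    box_lo: int = 1
    box_hi: int = 60
    mean_mut: float = 0.05
    mut_scale: float = 1.0
    indels: bool = False
    indel_prob: float = 0.5
    indel_region: str = "V"
    indel_len_mean: float = 5.0

    # execution
    seed: int = 0
    n_workers: int = 1
    log_level: str = "INFO"

    # -- builders --------------------------------------------------------

    def sw_scores(self) -> SwScores:
        return SwScores(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def threshold_config(self) -> ThresholdConfig:
        cfg = ThresholdConfig(lo_naive_hf=self.lo_hf, llr_table={int(k): float(v) for k, v in self.llr_table.items()})
        if self.hi_hf is not None:
            cfg.hi_naive_hf = lambda mut: self.hi_hf
        if self.point_hf is not None:
            cfg.point_hf = lambda mut: self.point_hf
        cfg.greedy_id = self.greedy_id
        return cfg.validate()

    def size_law_obj(self) -> SizeLaw:
        if self.size_law == "geometric":
            return SizeLaw("geometric", mean=self.size_mean)
        if self.size_law == "zipf":
            return SizeLaw("zipf", exponent=self.zipf_exponent, n_max=self.zipf_max)
        if self.size_law == "box":
            return SizeLaw("box", lo=self.box_lo, hi=self.box_hi)
        raise ValueError(f"unknown size law {self.size_law!r}")

    def germline_set(self):
        from .germline import fixture_germline_set, load_germline_set

        if self.v_genes is None:
            return fixture_germline_set()
        if self.d_genes is None or self.j_genes is None:
            raise ValueError("v_genes, d_genes and j_genes must all be given")
        return load_germline_set(self.v_genes, self.d_genes, self.j_genes, self.anchors)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
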