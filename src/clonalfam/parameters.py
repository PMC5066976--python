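"""Rearrangement parameter sets.

A :class:`ParameterSet` holds everything needed to build the VDJ HMM and to
drive the repertoire simulator: germline gene usage frequencies, exonuclease
deletion (erosion) length distributions for the four erodable gene ends,
non-templated (N) insertion length and base-composition distributions for
the two junctions, per-gene-position substitution probabilities, and the
empirical distribution of per-read mutation fractions.

Parameter sets are either estimated from data (see
:func:`clonalfam.sw.viterbi_train`) or constructed synthetically with
:func:`default_parameter_set` so that simulation and tests run without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
EROSION_ENDS = ("v_3p", "d_5p", "d_3p", "j_5p")
BOUNDARIES = ("vd", "dj")

#: which region each erodable gene end belongs to
EROSION_REGION = {"v_3p": "V", "d_5p": "D", "d_3p": "D", "j_5p": "J"}

_TOL = 1e-9


class ParameterError(ValueError):
    pass


def _check_dist(name: str, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError(f"{name}: expected a 1-d distribution")
    if (p < -_TOL).any() or (p > 1 + _TOL).any():
        raise ParameterError(f"{name}: probabilities outside [0, 1]")
    if abs(p.sum() - 1.0) > _TOL:
        raise ParameterError(f"{name}: sums to {p.sum()!r}, not 1")
    return p


@dataclass
class ParameterSet:
    """Empirical (or synthetic) distributions of the rearrangement process.

    Attributes
    ----------
    gene_usage : dict
        region -> {gene name -> probability}; sums to 1 per region.
    erosion_dists : dict
        gene end ("v_3p", "d_5p", "d_3p", "j_5p") -> {gene name -> array},
        index = deleted length.
    insertion_len_dists : dict
        boundary ("vd", "dj") -> array, index = insertion length (0-based,
        length 0 allowed).
    insertion_base_comp : dict
        boundary -> length-4 array of base frequencies in ACGT order.
    mut_rates : dict
        gene name -> per-position substitution probability array.
    mean_mut : float
        mean per-position substitution probability across the sample; used
        for N-state emissions.
    per_read_mut_dist : ndarray
        empirical sample of per-read mutation fractions; the simulator
        draws leaf divergence targets from it.
    """

    gene_usage: dict[str, dict[str, float]]
    erosion_dists: dict[str, dict[str, np.ndarray]]
    insertion_len_dists: dict[str, np.ndarray]
    insertion_base_comp: dict[str, np.ndarray]
    mut_rates: dict[str, np.ndarray]
    mean_mut: float
    per_read_mut_dist: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def validate(self) -> "ParameterSet":
        for region, usage in self.gene_usage.items():
            _check_dist(f"gene_usage[{region}]", np.array(list(usage.values())))
        for end, per_gene in self.erosion_dists.items():
            for gene, dist in per_gene.items():
                _check_dist(f"erosion_dists[{end}][{gene}]", dist)
        for boundary in BOUNDARIES:
            _check_dist(
                f"insertion_len_dists[{boundary}]", self.insertion_len_dists[boundary]
            )
            comp = _check_dist(
                f"insertion_base_comp[{boundary}]", self.insertion_base_comp[boundary]
            )
            if comp.size != 4:
                raise ParameterError(f"insertion_base_comp[{boundary}]: need 4 bases")
        for gene, rates in self.mut_rates.items():
            r = np.asarray(rates, dtype=float)
            if ((r < 0) | (r > 1)).any():
                raise ParameterError(f"mut_rates[{gene}]: outside [0, 1]")
        if not 0.0 <= self.mean_mut <= 1.0:
            raise ParameterError(f"mean_mut {self.mean_mut} outside [0, 1]")
        return self


def truncated_geometric(mean: float, support: int) -> np.ndarray:
    """Geometric law on {0, 1, ...} with the given mean, truncated to
    ``support`` outcomes and renormalized."""
    if support < 1:
        raise ParameterError("support must be >= 1")
    if mean <= 0:
        p = np.zeros(support)
        p[0] = 1.0
        return p
    q = mean / (mean + 1.0)  # continuation probability
    k = np.arange(support)
    p = (1 - q) * q**k
    return p / p.sum()


def default_parameter_set(
    germline, mean_mut: float = 0.05, seed: int = 0, n_mut_samples: int = 1000
) -> ParameterSet:
    """A synthetic stand-in for data-derived rearrangement parameters.

    Gene usage is near-uniform with mild biases, erosion lengths are
    geometric with mean 3, junction insertions geometric with mean 4, and
    per-position mutability factors are drawn once (from ``seed``) from a
    gamma law with unit mean, mimicking the position-to-position
    heterogeneity of somatic hypermutation.  Per-read mutation fractions
    follow a gamma surrogate with mean ``mean_mut``.
    """
    rng = np.random.default_rng(seed)
    gene_usage = {}
    for region in ("V", "D", "J"):
        genes = germline.region_genes(region)
        w = rng.dirichlet(np.full(len(genes), 8.0))
        gene_usage[region] = {g.name: float(p) for g, p in zip(genes, w)}

    erosion_dists: dict[str, dict[str, np.ndarray]] = {}
    for end in EROSION_ENDS:
        region = EROSION_REGION[end]
        per_gene = {}
        for g in germline.region_genes(region):
            # support capped well below gene length so D genes survive
            # erosion at both ends
            cap = min(len(g.seq) // 2, 12) + 1
            per_gene[g.name] = truncated_geometric(3.0, cap)
        erosion_dists[end] = per_gene

    insertion_len_dists = {b: truncated_geometric(4.0, 16) for b in BOUNDARIES}
    insertion_base_comp = {
        "vd": np.array([0.3, 0.2, 0.3, 0.2]),
        "dj": np.array([0.25, 0.25, 0.25, 0.25]),
    }

    mut_rates = {}
    for region in ("V", "D", "J"):
        for g in germline.region_genes(region):
            factors = rng.gamma(shape=2.0, scale=0.5, size=len(g.seq))
            mut_rates[g.name] = np.clip(mean_mut * factors, 0.0, 0.45)

    per_read = np.clip(
        rng.gamma(shape=3.0, scale=mean_mut / 3.0, size=n_mut_samples), 0.0, 0.45
    )
    return ParameterSet(
        gene_usage=gene_usage,
        erosion_dists=erosion_dists,
        insertion_len_dists=insertion_len_dists,
        insertion_base_comp=insertion_base_comp,
        mut_rates=mut_rates,
        mean_mut=mean_mut,
        per_read_mut_dist=per_read,
    ).validate()
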