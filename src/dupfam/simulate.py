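"""Synthetic-data generators matching the statistical assumptions of each
analysis stage.

Four generators:

* droplet counts under Poisson loading of a two-channel digital PCR,
* Poisson read depth over a genome with collapsed multi-copy loci,
* a two-species gene family evolving under a two-rate (K80) substitution
  process with optional interlocus gene conversion,
* CRISPR-edited amplicon reads with a stated indel spectrum.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    DepthTrack,
    MultipleAlignment,
    Region,
    RegionSet,
    SequenceRecord,
    validate_droplet_table,
)

__all__ = [
    "SaturationError",
    "DropletSimConfig",
    "DepthSimConfig",
    "FamilySimConfig",
    "AmpliconSimConfig",
    "simulate_droplets",
    "simulate_depth_track",
    "simulate_gene_family",
    "simulate_amplicon_reads",
    "true_indel_length",
    "true_class_counts",
    "random_additive_matrix",
]


class SaturationError(ValueError):
    """The implied positive-droplet fraction is indistinguishable from 1."""


# ---------------------------------------------------------------------------
# Droplet digital PCR

@dataclass
class DropletSimConfig:
    """Two-channel droplet plate at a known true diploid copy number.

    ``reference_lambda`` is the mean number of reference molecules per
    droplet; the target channel loading follows from the copy-number ratio:
    lambda_target = reference_lambda * true_cn / reference_copies.
    ``n_droplets`` defaults to a realistic per-well droplet count for a
    QX100-class reader.
    """

    true_cn: float
    reference_copies: int = 2
    reference_lambda: float = 0.2
    n_droplets: int = 20_000
    n_samples: int = 1
    population: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_cn < 0:
            raise ValueError("true_cn must be >= 0")
        if self.reference_copies < 1:
            raise ValueError("reference_copies must be >= 1")
        if self.reference_lambda <= 0:
            raise ValueError("reference_lambda must be positive")
        if self.n_droplets < 1 or self.n_samples < 1:
            raise ValueError("n_droplets and n_samples must be positive")

    @property
    def target_lambda(self) -> float:
        return self.reference_lambda * self.true_cn / self.reference_copies


def simulate_droplets(cfg: DropletSimConfig) -> pd.DataFrame:
    """Draw positives ~ Binomial(n_droplets, 1 - exp(-lambda)) per channel."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for lam in (cfg.target_lambda, cfg.reference_lambda):
        p = 1.0 - math.exp(-lam)
        if p >= 1.0 - 1e-12:
            raise SaturationError(
                f"channel loading lambda={lam:.3g} saturates the plate "
                f"(positive fraction {p:.12f})"
            )
    for i in range(cfg.n_samples):
        sample = f"{cfg.population}_{i + 1:03d}"
        for channel, lam in (("target", cfg.target_lambda), ("reference", cfg.reference_lambda)):
            p = 1.0 - math.exp(-lam)
            positives = int(rng.binomial(cfg.n_droplets, p))
            rows.append((sample, cfg.population, channel, positives, cfg.n_droplets))
    df = pd.DataFrame(rows, columns=["sample_id", "population", "channel", "positives", "total"])
    return validate_droplet_table(df, source="simulate_droplets")


# ---------------------------------------------------------------------------
# Read depth over a collapsed multi-copy locus

@dataclass
class DepthSimConfig:
    """Genome with Poisson depth and labeled loci of elevated copy multiplicity.

    ``multiplicities[label]`` is the number of haploid copies whose reads
    collapse onto that reference locus; the diploid background is 2.
    """

    genome_length: int
    coverage: float
    paralog_regions: RegionSet
    multiplicities: dict[str, float] = field(default_factory=dict)
    contig: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for region in self.paralog_regions:
            if region.contig != self.contig:
                raise ValueError(f"region {region.label} is not on {self.contig}")
            if region.start < 0 or region.end > self.genome_length:
                raise ValueError(f"region {region.label} outside the genome")
            m = self.multiplicities.get(region.label, 2.0)
            if m < 0:
                raise ValueError(f"multiplicity for {region.label} must be >= 0")


def simulate_depth_track(cfg: DepthSimConfig) -> tuple[DepthTrack, RegionSet]:
    """Depth at base i ~ Poisson(coverage * m_i / 2), background m = 2."""
    rng = np.random.default_rng(cfg.seed)
    mult = np.full(cfg.genome_length, 2.0)
    for region in cfg.paralog_regions:
        mult[region.start : region.end] = cfg.multiplicities.get(region.label, 2.0)
    lam = cfg.coverage * mult / 2.0
    depths = rng.poisson(lam).astype(np.int64)
    return DepthTrack(cfg.contig, 0, depths), cfg.paralog_regions


# ---------------------------------------------------------------------------
# Gene family under K80 substitution with gene conversion

_BASES = np.array(list("ACGT"))
# transition partner of A,C,G,T (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])


@dataclass
class FamilySimConfig:
    """A gene family duplicated before a two-species split.

    History: one ancestral gene duplicates into ``n_paralogs`` copies at
    ``duplication_depth`` (time units before the present), each paralog
    lineage then splits into the two species at ``speciation_depth``.
    Branch lengths in expected substitutions per site are
    ``substitution_rate * duration``. After speciation, interlocus gene
    conversion overwrites a uniformly placed tract of one paralog with the
    homologous tract of a within-species donor paralog.
    """

    n_paralogs: int = 4
    root_length: int = 2_000
    substitution_rate: float = 1.0
    kappa: float = 2.0
    speciation_depth: float = 0.05
    duplication_depth: float = 0.15
    gene_conversion_rate: float = 0.0
    conversion_tract_fraction: float = 0.3
    species_names: tuple[str, str] = ("spA", "spB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_paralogs < 1:
            raise ValueError("n_paralogs must be >= 1")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if min(self.substitution_rate, self.kappa, self.gene_conversion_rate) < 0:
            raise ValueError("rates must be >= 0")
        if not (0 < self.conversion_tract_fraction <= 1):
            raise ValueError("conversion_tract_fraction must be in (0, 1]")
        if self.duplication_depth <= self.speciation_depth:
            raise ValueError("duplication must precede speciation (duplication_depth > speciation_depth)")
        if self.speciation_depth < 0:
            raise ValueError("depths must be >= 0")


def _k80_substitution_probs(d: float, kappa: float) -> tuple[float, float]:
    """Per-site probabilities (P(transition), P(each transversion)) after a
    branch of ``d`` expected substitutions per site under K80."""
    if d == 0:
        return 0.0, 0.0
    # alpha*t and beta*t from d = (alpha + 2 beta) t and alpha/beta = kappa
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = math.exp(-4.0 * beta_t)
    e2 = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded (0-3) sequence along a branch of length ``d``."""
    p_ts, p_tv = _k80_substitution_probs(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ts_mask = u < p_ts
    out[ts_mask] = _TRANSITION[seq[ts_mask]]
    tv_mask = (u >= p_ts) & (u < p_ts + 2.0 * p_tv)
    if tv_mask.any():
        # choose one of the two transversion partners uniformly
        offsets = rng.integers(0, 2, size=int(tv_mask.sum()))
        cur = seq[tv_mask]
        partner = np.where(
            cur % 2 == 0,  # purines A(0), G(2) -> pyrimidines C(1), T(3)
            np.where(offsets == 0, 1, 3),
            np.where(offsets == 0, 0, 2),  # pyrimidines -> purines
        )
        out[tv_mask] = partner
    return out


def simulate_gene_family(cfg: FamilySimConfig) -> MultipleAlignment:
    """Simulate the family alignment; record ids are ``<species>_P<k>``."""
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.root_length
    ancestor = rng.integers(0, 4, size=n_sites)

    pre_speciation = cfg.substitution_rate * (cfg.duplication_depth - cfg.speciation_depth)
    post_speciation = cfg.substitution_rate * cfg.speciation_depth

    tips: dict[tuple[str, str], np.ndarray] = {}
    for k in range(cfg.n_paralogs):
        paralog = f"P{k + 1}"
        paralog_ancestor = _evolve(ancestor, pre_speciation, cfg.kappa, rng)
        for species in cfg.species_names:
            tips[(species, paralog)] = _evolve(paralog_ancestor, post_speciation, cfg.kappa, rng)

    # gene conversion after the split: events per tip lineage ~ Poisson(rate)
    if cfg.gene_conversion_rate > 0 and cfg.n_paralogs > 1:
        tract = max(1, round(cfg.conversion_tract_fraction * n_sites))
        events: list[tuple[str, str]] = []
        for key in tips:
            events.extend([key] * int(rng.poisson(cfg.gene_conversion_rate)))
        rng.shuffle(events)
        for species, paralog in events:
            donors = [p for (sp, p) in tips if sp == species and p != paralog]
            # dict preserves insertion order; donor choice is seeded
            donor = donors[int(rng.integers(0, len(donors)))]
            start = int(rng.integers(0, n_sites - tract + 1))
            recipient = tips[(species, paralog)]
            recipient[start : start + tract] = tips[(species, donor)][start : start + tract]

    records, species_labels, paralog_labels = [], [], []
    for (species, paralog), encoded in tips.items():
        seq = "".join(_BASES[encoded])
        records.append(SequenceRecord(f"{species}_{paralog}", seq, alphabet="dna"))
        species_labels.append(species)
        paralog_labels.append(paralog)
    return MultipleAlignment(records, species_labels, paralog_labels)


# ---------------------------------------------------------------------------
# CRISPR amplicon reads

@dataclass
class AmpliconSimConfig:
    """Edited amplicon reads: each read is the reference, or carries one
    indel of a length drawn from ``indel_spectrum`` at the cut site."""

    reference: SequenceRecord
    cut_site: int
    n_reads: int
    indel_spectrum: list[tuple[int, float]]
    unedited_fraction: float = 0.0
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cut_site < len(self.reference.sequence)):
            raise ValueError("cut_site outside the reference")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        total_p = self.unedited_fraction + sum(p for _, p in self.indel_spectrum)
        if not math.isclose(total_p, 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities must sum to 1 (got {total_p})")
        if any(p < 0 for _, p in self.indel_spectrum) or self.unedited_fraction < 0:
            raise ValueError("probabilities must be non-negative")
        if any(length == 0 for length, _ in self.indel_spectrum):
            raise ValueError("indel length 0 is not an edit")
        for length, _ in self.indel_spectrum:
            if length < 0 and -length >= len(self.reference.sequence):
                raise ValueError(f"deletion of {-length} bp longer than the reference")
        if not (0 <= self.substitution_error_rate < 1):
            raise ValueError("substitution_error_rate must be in [0, 1)")


def simulate_amplicon_reads(cfg: AmpliconSimConfig) -> list[SequenceRecord]:
    """Generate reads; the true indel length is carried in each record's
    description as ``indel=<signed int>`` (0 for unedited)."""
    rng = np.random.default_rng(cfg.seed)
    ref = cfg.reference.sequence.upper()
    outcomes = [0] + [length for length, _ in cfg.indel_spectrum]
    probs = [cfg.unedited_fraction] + [p for _, p in cfg.indel_spectrum]
    choices = rng.choice(len(outcomes), size=cfg.n_reads, p=probs)
    reads = []
    for i, choice in enumerate(choices):
        indel = outcomes[int(choice)]
        if indel == 0:
            seq = ref
        elif indel > 0:
            insert = "".join(_BASES[rng.integers(0, 4, size=indel)])
            seq = ref[: cfg.cut_site] + insert + ref[cfg.cut_site :]
        else:
            # center the deleted tract on the cut site, clipped to the reference
            del_len = -indel
            start = max(0, min(cfg.cut_site - del_len // 2, len(ref) - del_len))
            seq = ref[:start] + ref[start + del_len :]
        if cfg.substitution_error_rate > 0:
            arr = np.array(list(seq))
            err = rng.random(arr.size) < cfg.substitution_error_rate
            if err.any():
                arr[err] = _BASES[rng.integers(0, 4, size=int(err.sum()))]
                seq = "".join(arr)
        reads.append(
            SequenceRecord(f"read_{i + 1:06d}", seq, description=f"indel={indel}", alphabet="dna")
        )
    return reads


# ---------------------------------------------------------------------------
# Random additive distance matrices (inputs for distance-based tree building)

def random_additive_matrix(
    n_leaves: int,
    seed: int = 0,
    min_branch: float = 0.1,
    max_branch: float = 1.0,
) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """Leaf-to-leaf path distances of a random unrooted binary tree.

    Returns (labels, distance matrix, true non-trivial splits). Splits are
    frozensets of leaf labels, normalized to the side not containing the
    lexicographically smallest label. Branch lengths are uniform in
    [min_branch, max_branch], so the matrix is strictly additive.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1:02d}" for i in range(n_leaves)]

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    # leaves are 0..n-1; internal nodes count upward from n_leaves
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n_leaves + 1)}
    center = n_leaves
    for leaf in range(3):
        w = blen()
        adj[leaf][center] = w
        adj[center][leaf] = w
    next_node = n_leaves + 1
    for leaf in range(3, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(0, len(edges)))]
        mid = next_node
        next_node += 1
        adj[mid] = {}
        del adj[u][v], adj[v][u]
        for node, w in ((u, blen()), (v, blen())):
            adj[mid][node] = w
            adj[node][mid] = w
        adj[leaf] = {}
        w = blen()
        adj[leaf][mid] = w
        adj[mid][leaf] = w

    def distances_from(source: int) -> dict[int, float]:
        dist = {source: 0.0}
        stack = [source]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        return dist

    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        dist = distances_from(i)
        for j in range(n_leaves):
            D[i, j] = dist[j]

    def leaves_in_component(start: int, banned: tuple[int, int]) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if (node, nbr) == banned or (nbr, node) == banned:
                    continue
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return {x for x in seen if x < n_leaves}

    splits: set[frozenset] = set()
    for u in adj:
        for v in adj[u]:
            if u < v:
                side = leaves_in_component(u, (u, v))
                if 2 <= len(side) <= n_leaves - 2:
                    names = {labels[i] for i in side}
                    if labels[0] in names:
                        names = set(labels) - names
                    splits.add(frozenset(names))
    return labels, D, splits


def true_indel_length(read: SequenceRecord) -> int:
    """Recover the simulator's ground-truth indel length from a read."""
    for token in read.description.split():
        if token.startswith("indel="):
            return int(token[6:])
    raise ValueError(f"read {read.id} carries no ground-truth indel tag")


def true_class_counts(reads: list[SequenceRecord]) -> dict[str, int]:
    """Ground-truth unedited/in-frame/frameshift counts for simulated reads."""
    counts = {"unedited": 0, "in_frame": 0, "frameshift": 0}
    for read in reads:
        length = true_indel_length(read)
        if length == 0:
            counts["unedited"] += 1
        elif length % 3 == 0:
            counts["in_frame"] += 1
        else:
            counts["frameshift"] += 1
    return counts
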