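"""Synthetic-data generator for the in vitro mutation-accumulation experiment.

Emulates a serial-passage experiment with a hypermutator strain: starting
from a single founder genome, every culture is split in two each day and a
consensus genome is recorded for every sample.  Mutations accrue on each
branch as a Poisson number of substitutions per genome per day, applied at
distinct positions; the mutation spectrum is biased toward the
A:T -> C:G transversions characteristic of a mutT-deficient strain.  A
configurable fraction of samples is marked "observed" to emulate partial
sequencing success.

Mutation is modeled at the consensus level — one genome per node — which
is appropriate because a daily single-colony bottleneck fixes each
lineage's consensus and within-population diversity is vanishingly rare at
any specific site.  The generator returns the sequences, the realized true
tree (branch lengths = realized mutation counts), and per-sample metadata,
so every downstream module can be exercised without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from sabench.design import ExperimentDesign, build_design_tree
from sabench.treeio import LabeledTree, ValidationError

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_experiment",
    "mutate_genome",
    "hamming_diffs",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = _BASES
#: mutT-lesion transversion targets, preserving strand complementarity
_BIASED_TARGET = {int(_A): int(_C), int(_T): int(_G)}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated mutation-accumulation experiment.

    Attributes
    ----------
    days, split:
        Experiment schedule (8 days of binary splits by default, i.e.
        255 samples).
    genome_length:
        Genome size in bases.  100 kb by default for desk-scale runs; a
        realistic enterobacterial genome is ~4.6 Mb.
    mu:
        Expected mutations per genome per day.  Default 3.3, the rate
        observed in the hypermutator experiment (the plate-assay
        expectation is ~5.4).
    at_to_gc_bias:
        Probability that a mutation is an A->C / T->G transversion at a
        uniformly chosen A/T site (mutT spectrum).  Default 0.9.
    seq_success_prob:
        Per-sample probability of successful sequencing; the default
        101/255 emulates the experiment's 101 sequenced samples out of
        255.  Ignored when ``observed_names`` is given.
    observed_names:
        Optional explicit list of observed samples.
    fixed_count:
        If true, every branch receives exactly ``round(mu)`` mutations
        instead of a Poisson draw — an underdispersed variant.
    seed:
        Seed for the single PCG64 stream driving all randomness.
    """

    days: int = 8
    split: int = 2
    genome_length: int = 100_000
    mu: float = 3.3
    at_to_gc_bias: float = 0.9
    seq_success_prob: float = 101 / 255
    observed_names: Optional[tuple[str, ...]] = None
    fixed_count: bool = False
    root_name: str = "S"
    root_genome: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValidationError("genome_length must be >= 1")
        if self.mu < 0:
            raise ValidationError("mu must be >= 0")
        for p, label in [
            (self.at_to_gc_bias, "at_to_gc_bias"),
            (self.seq_success_prob, "seq_success_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{label} must be in [0, 1], got {p}")
        if self.root_genome is not None and len(self.root_genome) != self.genome_length:
            raise ValidationError("root_genome length must equal genome_length")


@dataclass
class SimulatedExperiment:
    """Result of :func:`simulate_experiment`.

    ``sequences`` maps every sample name (all of them, observed or not) to
    its consensus genome; ``truth`` is the realized tree with branch
    lengths equal to the number of mutations on each branch; ``metadata``
    is a per-sample table with columns name, day, observed,
    realized_branch_muts.
    """

    sequences: dict[str, str]
    truth: LabeledTree
    metadata: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def observed_names(self) -> list[str]:
        return list(self.metadata.loc[self.metadata.observed, "name"])

    def observed_sequences(self) -> dict[str, str]:
        return {name: self.sequences[name] for name in self.observed_names}


def _mutate_array(
    arr: np.ndarray, n_mut: int, at_to_gc_bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply ``n_mut`` substitutions at distinct positions of ``arr`` (in place)."""
    length = arr.size
    if n_mut > length:
        raise ValidationError(f"cannot place {n_mut} mutations on {length} sites")
    if at_to_gc_bias > 0 and not np.isin(arr, (_A, _T)).any():
        warnings.warn("no A/T sites available; using unbiased spectrum", stacklevel=3)
        at_to_gc_bias = 0.0
    used: set[int] = set()
    for _ in range(n_mut):
        biased = rng.random() < at_to_gc_bias
        pos = -1
        for _try in range(64):  # rejection sampling; exact fallback below
            cand = int(rng.integers(0, length))
            if cand in used:
                continue
            if biased and arr[cand] not in _BIASED_TARGET:
                continue
            pos = cand
            break
        if pos < 0:
            wanted = np.isin(arr, (_A, _T)) if biased else np.ones(length, bool)
            if used:
                wanted[list(used)] = False
            free = np.flatnonzero(wanted)
            if free.size == 0:  # all A/T sites consumed mid-branch
                biased = False
                wanted = np.ones(length, bool)
                wanted[list(used)] = False
                free = np.flatnonzero(wanted)
            pos = int(rng.choice(free))
        used.add(pos)
        if biased:
            arr[pos] = _BIASED_TARGET[int(arr[pos])]
        else:
            # uniform among the three other bases
            others = _BASES[_BASES != arr[pos]]
            arr[pos] = others[int(rng.integers(0, 3))]
    return arr


def mutate_genome(
    seq: str, n_mut: int, at_to_gc_bias: float, rng: np.random.Generator
) -> str:
    """Return ``seq`` with exactly ``n_mut`` substitutions at distinct positions.

    With probability ``at_to_gc_bias`` a mutation picks a uniformly chosen
    A or T site and applies the mutT transversion (A->C, T->G); otherwise
    a uniform site is changed to a uniform different base.  Deterministic
    given the generator state.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    _mutate_array(arr, n_mut, at_to_gc_bias, rng)
    return arr.tobytes().decode("ascii")


def hamming_diffs(seq_a: str, seq_b: str, return_skipped: bool = False):
    """Count positions where two equal-length genomes differ.

    Positions where either sequence carries a non-ACGT symbol are skipped;
    pass ``return_skipped=True`` to also get the number of skipped sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a = np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)
    ok = np.isin(a, _BASES) & np.isin(b, _BASES)
    diffs = int(((a != b) & ok).sum())
    if return_skipped:
        return diffs, int((~ok).sum())
    return diffs


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the mutation-accumulation simulation described by ``config``.

    The founder genome is drawn uniformly over {A,C,G,T} (or supplied);
    each daughter genome equals its parent with ``K ~ Poisson(mu)``
    substitutions (or exactly ``round(mu)`` in fixed-count mode) applied
    at distinct positions.  The realized tree mirrors the design tree with
    realized mutation counts as branch lengths.  Reproducible given
    ``config.seed``.
    """
    if config.genome_length < config.mu * 10:
        warnings.warn(
            "genome_length is within 10x of the per-branch mutation count; "
            "repeated hits (homoplasy) are no longer negligible",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    design = ExperimentDesign(config.days, config.split, config.root_name)
    truth = build_design_tree(design)

    if config.root_genome is not None:
        root_arr = np.frombuffer(
            config.root_genome.encode("ascii"), dtype=np.uint8
        ).copy()
        if not np.isin(root_arr, _BASES).all():
            raise ValidationError("root_genome must contain only A, C, G, T")
    else:
        root_arr = _BASES[rng.integers(0, 4, size=config.genome_length)]

    arrays: dict[str, np.ndarray] = {config.root_name: root_arr}
    realized: dict[str, int] = {config.root_name: 0}
    for node in truth.preorder():
        parent_arr = arrays[node.names[0]]
        for child in node.children:
            if config.fixed_count:
                k = int(round(config.mu))
            else:
                k = int(rng.poisson(config.mu))
            child_arr = _mutate_array(parent_arr.copy(), k, config.at_to_gc_bias, rng)
            name = child.names[0]
            arrays[name] = child_arr
            realized[name] = k
            child.blen = float(k)

    all_names = [node.names[0] for node in truth.preorder()]
    if config.observed_names is not None:
        unknown = set(config.observed_names) - set(all_names)
        if unknown:
            raise ValidationError(f"unknown observed names: {sorted(unknown)!r}")
        observed = set(config.observed_names)
    else:
        flags = rng.random(len(all_names)) < config.seq_success_prob
        observed = {name for name, f in zip(all_names, flags) if f}

    sequences = {
        name: arr.tobytes().decode("ascii") for name, arr in arrays.items()
    }
    days = {node.names[0]: node.day for node in truth.preorder()}
    metadata = pd.DataFrame(
        {
            "name": all_names,
            "day": [days[n] for n in all_names],
            "observed": [n in observed for n in all_names],
            "realized_branch_muts": [realized[n] for n in all_names],
        }
    )
    return SimulatedExperiment(sequences, truth, metadata, config)


def write_fasta(experiment: SimulatedExperiment, path) -> int:
    """Write one FASTA record per *observed* sample; returns the count."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in experiment.observed_sequences().items()
    ]
    return seqio_write(records, str(path), "fasta")
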