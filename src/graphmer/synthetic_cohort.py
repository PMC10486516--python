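"""Class-conditional Markov-chain read simulator for labeled test cohorts.

Real 16S cohorts are not redistributable at desk scale, so benchmarks and
tests here run on synthetic cohorts whose disease signal is planted
exactly where the De Bruijn featurization looks: in the (m+1)-mer
transition frequencies of the reads.  Healthy samples draw reads from an
order-m Markov chain over {A,C,G,T}; diseased samples draw from the same
chain with the probability of one designated next base raised by ``delta``
in a chosen set of m-mer contexts (other bases renormalized).  With
m equal to the k-mer length, the two classes' expected feature vectors
differ only in the columns matching a perturbed (context, base) pair.

The generator deliberately models nothing else — no sequencing error,
chimeras or taxonomic structure — because the statistical object under
test is the transition-frequency signal itself.

Seeding is hierarchical (cohort -> class -> sample) via
``numpy.random.SeedSequence`` so any subset of samples is reproducible
independently of the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .debruijn import BASES, id_to_kmer, kmer_to_id
from .fastq_io import CleanSample

__all__ = [
    "CohortDesign",
    "build_class_matrices",
    "simulate_sample",
    "generate_cohort",
    "simulate_cohort",
]

#: Quality character written for every base; quality is never consumed.
DUMMY_QUALITY = "I"


@dataclass
class CohortDesign:
    """Design of a two-class synthetic cohort.

    Parameters
    ----------
    n_per_class : samples per class (cohort size is twice this).
    reads_per_sample, read_length : library size and read length; the
        defaults (500 reads of 150 bp) are desk-scale stand-ins for V4
        amplicon libraries.
    order : Markov order m; default 3 so the planted signal is fully
        visible to k=3 features and partially to k=4,5.
    delta : probability added to the designated base in each perturbed
        context, in [0, 0.25); 0 means the classes are identical.
    n_perturbed_contexts : how many m-mer contexts carry signal when
        ``perturbed_contexts`` is not given explicitly.
    base_transition : optional explicit (4^m, 4) stochastic matrix for the
        healthy class; drawn from a Dirichlet around uniform if omitted.
    perturbed_contexts : optional explicit mapping context m-mer ->
        designated next base, e.g. {"ACG": "T"}.
    seed : master seed for every random choice the design implies.
    """

    n_per_class: int = 100
    reads_per_sample: int = 500
    read_length: int = 150
    order: int = 3
    delta: float = 0.12
    n_perturbed_contexts: int = 8
    base_transition: Optional[np.ndarray] = None
    perturbed_contexts: Optional[dict[str, str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.delta < 0.25:
            raise ValueError(f"delta must be in [0, 0.25), got {self.delta}")
        if self.order < 1:
            raise ValueError("Markov order must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def to_config_text(self) -> str:
        """Serialize the scalar design parameters as key = value lines."""
        skip = {"base_transition"}
        lines = []
        for key, value in asdict(self).items():
            if key in skip:
                continue
            if key == "perturbed_contexts" and value is not None:
                value = ",".join(f"{c}>{b}" for c, b in sorted(value.items()))
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"


def _default_healthy_matrix(design: CohortDesign) -> np.ndarray:
    """Mildly non-uniform rows: Dirichlet(40) around the uniform simplex
    center, so background transition structure exists but is weak."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xBA5E]))
    return rng.dirichlet([40.0] * 4, size=4**design.order)


def _default_perturbed_contexts(design: CohortDesign) -> dict[str, str]:
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xC0DE]))
    n_ctx = 4**design.order
    n_pick = min(design.n_perturbed_contexts, n_ctx)
    contexts = rng.choice(n_ctx, size=n_pick, replace=False)
    return {
        id_to_kmer(int(ctx), design.order): BASES[int(rng.integers(4))]
        for ctx in contexts
    }


def build_class_matrices(design: CohortDesign) -> tuple[np.ndarray, np.ndarray]:
    """(healthy, diseased) transition matrices, shape (4^m, 4) each.

    The diseased matrix equals the healthy one except that in each
    perturbed context the designated base's probability is raised by
    delta and the remaining three renormalized to keep the row summing
    to 1.  delta = 0 returns two equal matrices.
    """
    healthy = (
        np.asarray(design.base_transition, dtype=float)
        if design.base_transition is not None
        else _default_healthy_matrix(design)
    )
    if healthy.shape != (4**design.order, 4):
        raise ValueError(
            f"base transition matrix must have shape ({4**design.order}, 4)"
        )
    if not np.allclose(healthy.sum(axis=1), 1.0) or (healthy < 0).any():
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")
    contexts = (
        design.perturbed_contexts
        if design.perturbed_contexts is not None
        else _default_perturbed_contexts(design)
    )
    diseased = healthy.copy()
    if design.delta == 0.0:
        return healthy, diseased
    for context, base in contexts.items():
        row = kmer_to_id(context)
        col = kmer_to_id(base)
        target = healthy[row, col] + design.delta
        if target > 1.0:
            raise ValueError(
                f"context {context}->{base}: shift by {design.delta} exceeds 1"
            )
        others = np.arange(4) != col
        rest = healthy[row, others]
        scale = (1.0 - target) / rest.sum()
        if scale < 0:
            raise ValueError(
                f"context {context}->{base}: shift leaves negative probability"
            )
        diseased[row, col] = target
        diseased[row, others] = rest * scale
    return healthy, diseased


def simulate_sample(
    matrix: np.ndarray,
    reads: int,
    length: int,
    rng: np.random.Generator,
    sample_id: str = "sample",
    label: Optional[int] = None,
) -> CleanSample:
    """Draw ``reads`` independent reads from an order-m Markov chain.

    The first m bases of each read are uniform; every subsequent base is
    drawn from the matrix row of the preceding m-mer context.  Fully
    deterministic given the generator state.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_ctx = matrix.shape[0]
    m = int(round(np.log(n_ctx) / np.log(4)))
    if 4**m != n_ctx or matrix.shape[1] != 4:
        raise ValueError(f"matrix shape {matrix.shape} is not (4^m, 4)")
    cdf = matrix.cumsum(axis=1)
    cdf[:, -1] = 1.0  # guard against float drift in the last column
    codes = np.empty((reads, length), dtype=np.int64)
    head = min(m, length)
    codes[:, :head] = rng.integers(0, 4, size=(reads, head))
    if length > m:
        powers = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
        ctx = codes[:, :m] @ powers
        for pos in range(m, length):
            u = rng.random(reads)
            nxt = (u[:, None] > cdf[ctx]).sum(axis=1)
            codes[:, pos] = nxt
            # roll the context window: drop the oldest base, append nxt
            ctx = (ctx % 4 ** (m - 1)) * 4 + nxt
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    read_strings = [
        base_arr[row].tobytes().decode("ascii") for row in codes
    ]
    return CleanSample(sample_id=sample_id, reads=read_strings, label=label)


def generate_cohort(design: CohortDesign) -> list[CleanSample]:
    """Generate the full labeled cohort in memory.

    Healthy samples (label 0) come first, then diseased (label 1); each
    sample has its own child seed so the cohort is reproducible and any
    prefix of it is stable under changes to later samples.
    """
    healthy_m, diseased_m = build_class_matrices(design)
    root = np.random.SeedSequence([design.seed, 0x5EED])
    class_seqs = root.spawn(2)
    samples: list[CleanSample] = []
    for label, (matrix, class_seq, tag) in enumerate(
        [(healthy_m, class_seqs[0], "h"), (diseased_m, class_seqs[1], "d")]
    ):
        for i, child in enumerate(class_seq.spawn(design.n_per_class)):
            rng = np.random.default_rng(child)
            samples.append(
                simulate_sample(
                    matrix,
                    design.reads_per_sample,
                    design.read_length,
                    rng,
                    sample_id=f"sample_{tag}{i:04d}",
                    label=label,
                )
            )
    return samples


def simulate_cohort(design: CohortDesign, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write the cohort as 4-line FASTQ files plus a labels CSV.

    Every read gets a constant dummy quality line (quality carries no
    information downstream).  Regenerating with the same design yields
    byte-identical files.  Returns (fastq paths, labels path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_cohort(design)
    fastq_paths: list[Path] = []
    labels_path = out_dir / "labels.csv"
    with labels_path.open("w") as lab:
        lab.write("sample_id,diagnosis\n")
        for sample in samples:
            path = out_dir / f"{sample.sample_id}.fastq"
            with path.open("w") as fh:
                for i, read in enumerate(sample.reads):
                    fh.write(
                        f"@{sample.sample_id}.{i}\n{read}\n+\n"
                        f"{DUMMY_QUALITY * len(read)}\n"
                    )
            lab.write(f"{sample.sample_id},{'CD' if sample.label else 'no'}\n")
            fastq_paths.append(path)
    (out_dir / "design.cfg").write_text(design.to_config_text())
    return fastq_paths, labels_path
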