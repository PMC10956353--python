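"""Long-read generation for the simulated community.

Two backends exist.  The internal generator produces ground-truth-annotated
FASTQ directly: read lengths follow a log-normal, start positions are uniform
on either strand, and errors are injected at a configurable per-base rate
with a substitution:insertion:deletion ratio.  Read names encode the source
genome, coordinates and strand so downstream evaluation can recover the true
layout.  The external backend emits (but never executes) the shell commands
of a PacBio-style pipeline — pbsim3 per genome, SAM-to-BAM conversion with
samtools, and circular consensus calling with ccs for the HiFi platform.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

PLATFORMS = ("hifi", "ont")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadModel:
    """Read-length and error model of a long-read platform."""

    platform: str
    mean_length: float
    sd_length: float
    error_rate: float
    error_ratio: tuple[float, float, float]  # substitution : insertion : deletion
    min_length: int = 100
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must lie in [0, 1)")
        if not self.mean_length > 0:
            raise ValueError("mean read length must be > 0")

    @property
    def error_probs(self) -> np.ndarray:
        r = np.asarray(self.error_ratio, dtype=float)
        return r / r.sum()


def model_for(platform: str, error_rate: float | None = None) -> ReadModel:
    """Default read model for a platform (internal-generator conventions)."""
    if platform == "hifi":
        model = ReadModel("hifi", 10_000, 2_000, 0.002, (6, 50, 54), quality_char="I")
    elif platform == "ont":
        model = ReadModel("ont", 20_000, 10_000, 0.05, (39, 24, 36), quality_char="+")
    else:
        raise ValueError(f"platform must be one of {PLATFORMS}, got {platform!r}")
    if error_rate is not None:
        model.error_rate = error_rate
    return model


def compute_read_count(depth: float, genome_length: int, model: ReadModel) -> int:
    """Number of reads needed for a target fold coverage (at least one)."""
    if depth <= 0 or genome_length <= 0:
        raise ValueError("depth and genome length must be > 0")
    return max(1, round(depth * genome_length / model.mean_length))


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    quality: str


def _lognormal_lengths(model: ReadModel, n: int, upper: int, rng) -> np.ndarray:
    sigma2 = np.log1p((model.sd_length / model.mean_length) ** 2)
    mu = np.log(model.mean_length) - sigma2 / 2.0
    lengths = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.clip(np.round(lengths).astype(int), min(model.min_length, upper), upper)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _inject_errors(seq: str, model: ReadModel, rng) -> str:
    if model.error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    k = rng.binomial(arr.size, model.error_rate)
    if k == 0:
        return seq
    positions = np.sort(rng.choice(arr.size, size=k, replace=False))[::-1]
    kinds = rng.choice(3, size=k, p=model.error_probs)  # 0 sub, 1 ins, 2 del
    out = arr.tolist()
    for pos, kind in zip(positions, kinds):
        if kind == 0:
            current = out[pos]
            choices = [b for b in _BASES.tolist() if b != current]
            out[pos] = choices[int(rng.integers(0, len(choices)))]
        elif kind == 1:
            out.insert(pos + 1, _BASES.tolist()[int(rng.integers(0, 4))])
        else:
            del out[pos]
    return b"".join(out).decode()


def simulate_reads(
    name: str, sequence: str, depth: float, model: ReadModel, rng
) -> list[FastqRead]:
    """Simulate reads over one linear genome at the given fold coverage.

    Read names follow ``<genome>_<start>_<end>_<strand>_<serial>`` with
    0-based half-open coordinates on the forward strand, giving the exact
    ground-truth layout.
    """
    genome_length = len(sequence)
    if genome_length < min(model.min_length, int(model.mean_length)):
        raise ValueError(
            f"genome {name!r} ({genome_length} bp) shorter than the minimum read length"
        )
    rng = np.random.default_rng(rng)
    n = compute_read_count(depth, genome_length, model)
    lengths = _lognormal_lengths(model, n, genome_length, rng)
    starts = rng.integers(0, genome_length - lengths + 1)
    strands = rng.integers(0, 2, size=n)
    reads: list[FastqRead] = []
    for serial, (start, length, fwd) in enumerate(zip(starts, lengths, strands)):
        start = int(start)
        end = start + int(length)
        fragment = sequence[start:end]
        strand = "+" if fwd else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        fragment = _inject_errors(fragment, model, rng)
        read_id = f"{name}_{start}_{end}_{strand}_{serial}"
        reads.append(FastqRead(read_id, fragment, model.quality_char * len(fragment)))
    return reads


def parse_read_name(read_id: str) -> tuple[str, int, int, str, int]:
    """Recover (genome, start, end, strand, serial) from a read name."""
    name, start, end, strand, serial = read_id.rsplit("_", 4)
    return name, int(start), int(end), strand, int(serial)


def write_fastq(reads, handle) -> None:
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, "w")
        close = True
    try:
        for r in reads:
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    finally:
        if close:
            handle.close()


def simulate_community_reads(spec, model: ReadModel, out_fastq, rng) -> int:
    """Simulate reads for every strain genome of a community manifest.

    Returns the total read count.  Genomes are read from the FASTA paths in
    the manifest; each strain is sequenced at its own depth.
    """
    rng = np.random.default_rng(rng)
    total = 0
    with open(out_fastq, "w") as fh:
        for member in spec.members:
            for strain in member.strains:
                record = next(SeqIO.parse(strain.genome_path, "fasta"))
                reads = simulate_reads(
                    strain.accession, str(record.seq), strain.depth, model, rng
                )
                write_fastq(reads, fh)
                total += len(reads)
    return total


@dataclass
class PlanStep:
    tool: str
    args: list[str]
    inputs: list[str]
    outputs: list[str]

    def command(self) -> str:
        return " ".join([self.tool] + self.args)


@dataclass
class CommandPlan:
    """An ordered external-tool pipeline; written to a script, never executed."""

    steps: list[PlanStep]

    def validate(self, preexisting) -> None:
        """Check every input is preexisting or produced by an earlier step."""
        available = set(preexisting)
        for i, step in enumerate(self.steps):
            for inp in step.inputs:
                if inp not in available:
                    raise ValueError(
                        f"step {i} ({step.tool}): input {inp!r} not available"
                    )
            available.update(step.outputs)

    def to_script(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#!/bin/sh\nset -eu\n")
            for step in self.steps:
                fh.write(step.command() + "\n")


def plan_external_pipeline(
    spec, model: ReadModel, output_dir, qshmm_model: str = "QSHMM-RSII.model"
) -> CommandPlan:
    """Plan the external read pipeline: pbsim3, then samtools, then ccs (HiFi).

    pbsim3 simulates continuous long reads per genome with the qshmm error
    model; samtools converts its SAM output to BAM; for the HiFi platform ccs
    then derives high-fidelity consensus reads.  For ONT no consensus step is
    emitted.
    """
    out = Path(output_dir)
    steps: list[PlanStep] = []
    for member in spec.members:
        for strain in member.strains:
            prefix = str(out / strain.accession)
            sam = f"{prefix}_0001.sam"
            bam = f"{prefix}_0001.bam"
            steps.append(
                PlanStep(
                    tool="pbsim",
                    args=[
                        "--strategy", "wgs",
                        "--method", "qshmm",
                        "--qshmm", qshmm_model,
                        "--depth", f"{strain.depth:g}",
                        "--genome", strain.genome_path,
                        "--pass-num", "10" if model.platform == "hifi" else "1",
                        "--prefix", prefix,
                    ],
                    inputs=[strain.genome_path],
                    outputs=[sam],
                )
            )
            steps.append(
                PlanStep(
                    tool="samtools",
                    args=["view", "-b", "-o", bam, sam],
                    inputs=[sam],
                    outputs=[bam],
                )
            )
            if model.platform == "hifi":
                fq = f"{prefix}.hifi.fastq.gz"
                steps.append(
                    PlanStep(
                        tool="ccs",
                        args=[bam, fq],
                        inputs=[bam],
                        outputs=[fq],
                    )
                )
    plan = CommandPlan(steps)
    plan.validate([s.genome_path for m in spec.members for s in m.strains])
    return plan
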