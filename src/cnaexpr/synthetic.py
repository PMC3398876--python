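"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates, at reduced scale, the data structure of an integrated SNP-array /
expression-array study of microdissected tumours: probe-level log2 ratios
carrying planted segmental deletions, homozygous deletions, gains and one
high-level amplification, plus a probe-specific amplification bias shared
with simulated amplified-normal controls; an expression matrix whose tumour
values can be coupled to copy number; and qPCR plates generated from a
log-linear standard curve.

One global seed spawns independent child seeds per stage (annotation,
ratios, expression, qPCR) so stages can be regenerated independently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copy_number import GeneCN, ProbeRatioMatrix

__all__ = [
    "GenomeSpec",
    "Event",
    "EventSpec",
    "CouplingSpec",
    "generate_annotation",
    "generate_probe_ratios",
    "generate_expression",
    "generate_qpcr_plate",
    "default_events",
]

EVENT_KINDS = ("deletion", "homozygous_deletion", "gain", "amplification")

#: qPCR calibrator dilution series, in gene copies.
CALIBRATOR_COPIES = (10, 100, 1_000, 10_000, 100_000)

#: Expression signal below which a transcript may drop out of detection.
DETECTION_FLOOR = 20.0


def _child_seeds(seed: int, n: int = 4):
    return np.random.SeedSequence(seed).spawn(n)


@dataclass(frozen=True)
class GenomeSpec:
    """Reduced-scale genome layout for simulation.

    Defaults give three chromosomes totalling 150 Mb carrying 200
    non-overlapping genes, of which 20 are labelled tumour suppressors (TSG)
    and 10 tumour promoters (TPG), with a uniform 200 kb probe grid —
    a miniature of a genome-wide SNP-array study.
    """

    chromosomes: tuple = (
        ("chr1", 60_000_000),
        ("chr2", 50_000_000),
        ("chr3", 40_000_000),
    )
    n_genes: int = 200
    n_tsg: int = 20
    n_tpg: int = 10
    probe_spacing: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.n_tsg + self.n_tpg > self.n_genes:
            raise ValueError("n_tsg + n_tpg must not exceed n_genes")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")


@dataclass(frozen=True)
class Event:
    """One planted copy-number event in one sample."""

    chrom: str
    start: int
    end: int
    kind: str
    true_copies: float

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("event start > end")
        if self.true_copies < 0:
            raise ValueError("true_copies must be >= 0")
        if self.kind in ("deletion", "homozygous_deletion") and self.true_copies >= 2:
            raise ValueError("deletion events need true_copies < 2")
        if self.kind == "gain" and self.true_copies <= 2:
            raise ValueError("gain events need true_copies > 2")
        if self.kind == "amplification" and self.true_copies < 5:
            raise ValueError("amplification means 5 or more copies")


@dataclass
class EventSpec:
    """Planted events per sample plus the noise model of the ratio matrix.

    ``amplification_bias_sd`` is the spread of the probe-specific bias that
    whole-genome amplification stamps identically onto tumours and
    amplified-normal controls.  ``homdel_floor`` keeps log2 defined for
    zero-copy events (array ratios never reach -inf in practice).
    """

    events: dict = field(default_factory=dict)  # sample -> [Event, ...]
    noise_sd: float = 0.15
    amplification_bias_sd: float = 0.3
    n_control_samples: int = 5
    homdel_floor: float = 0.05

    def __post_init__(self):
        if self.noise_sd < 0 or self.amplification_bias_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.n_control_samples < 0:
            raise ValueError("n_control_samples must be >= 0")
        if not (0 < self.homdel_floor < 2):
            raise ValueError("homdel_floor must be in (0, 2)")


@dataclass(frozen=True)
class CouplingSpec:
    """How tumour expression tracks copy number and planted regulation.

    ``coupled_fraction`` of genes have tumour means scaled by
    ``2**(assigned log2 ratio)``.  Independently, a fraction of genes is
    planted as up- or down-regulated by ``fold_up`` / ``fold_down`` in a
    random subset of tumours.  ``detection_dropout`` is the probability that
    a signal below the detection floor is called absent.
    """

    coupled_fraction: float = 0.3
    fold_up: float = 4.0
    fold_down: float = 0.25
    frac_up: float = 0.1
    frac_down: float = 0.1
    change_prob: float = 0.8
    detection_dropout: float = 0.1
    expr_noise_sd: float = 0.2  # sd of log2-scale multiplicative noise
    n_tumours: int = 8
    n_normals: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("coupled_fraction", "frac_up", "frac_down",
                     "change_prob", "detection_dropout"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fold_up <= 1 or not (0 < self.fold_down < 1):
            raise ValueError("fold_up must be > 1 and fold_down in (0, 1)")
        if self.n_normals < 2:
            raise ValueError("need >= 2 normal samples for call rules")


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(spec: GenomeSpec) -> pd.DataFrame:
    """Place non-overlapping genes on the genome and label TSG/TPG classes.

    Genes are distributed across chromosomes proportionally to length, each
    inside its own uniform slot so intervals never overlap.  Returns a
    DataFrame indexed by symbol with columns chrom, start, end, role
    (role in {"TSG", "TPG", "."}), sorted by (chrom, start).
    """
    rng = np.random.default_rng(_child_seeds(spec.seed)[0])
    total = sum(length for _, length in spec.chromosomes)
    counts = [int(round(spec.n_genes * length / total)) for _, length in spec.chromosomes]
    while sum(counts) > spec.n_genes:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < spec.n_genes:
        counts[int(np.argmin(counts))] += 1
    rows = []
    gi = 0
    for (chrom, length), n_c in zip(spec.chromosomes, counts):
        if n_c == 0:
            continue
        slot = length // n_c
        if slot < 3:
            raise ValueError(
                f"cannot pack {n_c} genes into {chrom} ({length} bp)"
            )
        for s in range(n_c):
            lo = s * slot + 1
            hi = min((s + 1) * slot, length)
            width = hi - lo
            glen = int(rng.integers(max(1, width // 10), max(2, width // 2)))
            start = int(rng.integers(lo, hi - glen))
            gi += 1
            rows.append((f"G{gi:04d}", chrom, start, start + glen))
    ann = pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end"])
    ann["role"] = "."
    labels = rng.choice(len(ann), size=spec.n_tsg + spec.n_tpg, replace=False)
    ann.loc[labels[: spec.n_tsg], "role"] = "TSG"
    ann.loc[labels[spec.n_tsg :], "role"] = "TPG"
    return ann.set_index("symbol")


# ---------------------------------------------------------------------------
# probe ratios


def default_events(
    genome: GenomeSpec, n_tumours: int = 8, seed: int = 0
) -> dict:
    """Recurrent planted events loosely shaped like a carcinoma cohort.

    A recurrent hemizygous deletion on chr1 (~75% of tumours, with a nested
    homozygous deletion in a few), a recurrent gain on chr2 (~50%), and a
    single >=5-copy amplification on chr3 in exactly one tumour.
    """
    rng = np.random.default_rng(seed)
    samples = [f"T{i + 1:02d}" for i in range(n_tumours)]
    events = {s: [] for s in samples}
    del_region = ("chr1", 10_000_001, 22_000_000)
    homdel_region = ("chr1", 14_000_001, 15_600_000)
    gain_region = ("chr2", 20_000_001, 30_000_000)
    amp_region = ("chr3", 8_000_001, 10_500_000)
    n_del = max(1, int(round(0.75 * n_tumours)))
    n_hom = max(1, n_del // 4)
    n_gain = max(1, int(round(0.5 * n_tumours)))
    del_samples = list(rng.choice(samples, size=n_del, replace=False))
    for s in del_samples:
        events[s].append(Event(*del_region, "deletion", 1.0))
    for s in rng.choice(del_samples, size=n_hom, replace=False):
        events[s].append(Event(*homdel_region, "homozygous_deletion", 0.0))
    for s in rng.choice(samples, size=n_gain, replace=False):
        events[s].append(Event(*gain_region, "gain", 3.0))
    amp_sample = samples[int(rng.integers(n_tumours))]
    events[amp_sample].append(Event(*amp_region, "amplification", 10.0))
    return events


def _probe_grid(genome: GenomeSpec) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.chromosomes:
        positions = np.arange(genome.probe_spacing, length + 1, genome.probe_spacing)
        for k, pos in enumerate(positions):
            rows.append(
                (f"{chrom}_p{k + 1:05d}", chrom, int(pos), "A" if k % 2 == 0 else "B")
            )
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "enzyme_set"])


def generate_probe_ratios(
    genome: GenomeSpec, events: EventSpec, seed: int = 0
):
    """Simulate probe-level log2 ratios with planted events and shared bias.

    Tumour ratio at probe p = log2(true_copies/2) + bias_p + N(0, noise_sd);
    each amplified-normal control = bias_p + N(0, noise_sd), with bias_p
    drawn once per probe from N(0, amplification_bias_sd).  Homozygous
    deletions are floored at ``events.homdel_floor`` copies.

    Returns (ProbeRatioMatrix, truth_segments, true_gene_copies) where
    truth_segments is a SEG-style DataFrame of constant-copy runs over the
    probe grid (per sample, with true_copies and the noise-free mean_log2)
    and true_gene_copies is reserved for callers that also hold annotation.
    """
    rng = np.random.default_rng(_child_seeds(seed)[1])
    probes = _probe_grid(genome)
    n_probes = len(probes)
    chrom_arr = probes["chrom"].to_numpy()
    pos_arr = probes["pos"].to_numpy()
    bias = rng.normal(0.0, events.amplification_bias_sd, size=n_probes)

    samples = list(events.events.keys())
    ratios = {}
    truth_rows = []
    copies_by_sample = {}
    for sample in samples:
        copies = np.full(n_probes, 2.0)
        for ev in events.events[sample]:
            in_ev = (chrom_arr == ev.chrom) & (pos_arr >= ev.start) & (pos_arr <= ev.end)
            if not in_ev.any():
                warnings.warn(
                    f"event {ev.kind} {ev.chrom}:{ev.start}-{ev.end} in "
                    f"{sample} covers no probes and is unrecoverable",
                    stacklevel=2,
                )
                continue
            copies[in_ev] = max(ev.true_copies, events.homdel_floor)
        copies_by_sample[sample] = copies
        signal = np.log2(copies / 2.0)
        ratios[sample] = signal + bias + rng.normal(0.0, events.noise_sd, n_probes)
        # constant-copy runs over the probe grid = planted truth segments
        for chrom in dict.fromkeys(chrom_arr):
            sel = np.flatnonzero(chrom_arr == chrom)
            c = copies[sel]
            breaks = np.flatnonzero(np.diff(c) != 0)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(c) - 1]])
            for a, b in zip(starts, ends):
                truth_rows.append(
                    (
                        sample,
                        chrom,
                        int(pos_arr[sel[a]]),
                        int(pos_arr[sel[b]]),
                        int(b - a + 1),
                        float(np.log2(c[a] / 2.0)),
                        float(c[a]),
                    )
                )
    controls = [f"C{i + 1}" for i in range(events.n_control_samples)]
    for ctrl in controls:
        ratios[ctrl] = bias + rng.normal(0.0, events.noise_sd, n_probes)
    matrix = ProbeRatioMatrix(
        probes=probes,
        ratios=pd.DataFrame(ratios),
        control_samples=tuple(controls),
    )
    truth_segments = pd.DataFrame(
        truth_rows,
        columns=["sample", "chrom", "start", "end", "n_probes", "seg_mean", "true_copies"],
    )
    return matrix, truth_segments, copies_by_sample


def true_gene_ratios(
    annotation: pd.DataFrame, truth_segments: pd.DataFrame
) -> GeneCN:
    """Noise-free gene-level log2 ratios implied by the planted truth."""
    from .copy_number import assign_gene_values

    return assign_gene_values(truth_segments, annotation)


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    annotation: pd.DataFrame,
    true_genecn: GeneCN | None,
    coupling: CouplingSpec,
):
    """Simulate a gene x sample expression matrix coupled to copy number.

    Normals share a per-gene log-normal baseline (median ~ the array target
    signal of 100).  A coupled gene's tumour mean is scaled by
    2**(assigned log2 ratio); planted UP/DOWN genes are scaled by
    fold_up/fold_down in a random subset of tumours.  Detection calls are
    absent with probability ``detection_dropout`` for signals below the
    detection floor, present otherwise.

    Returns (ExpressionMatrix, truth) where truth is the gene x tumour
    UP/DOWN/NC table implied by the deterministic planted factor (the call
    the rules would make at zero noise: factor > 2 -> UP, < 0.5 -> DOWN).
    """
    from .expression import ExpressionMatrix

    if coupling.n_normals < 2:
        raise ValueError("need >= 2 normals")
    rng = np.random.default_rng(_child_seeds(coupling.seed)[2])
    genes = annotation.index
    n_genes = len(genes)
    tumours = (
        list(true_genecn.ratios.columns[: coupling.n_tumours])
        if true_genecn is not None
        else [f"T{i + 1:02d}" for i in range(coupling.n_tumours)]
    )
    normals = [f"N{i + 1}" for i in range(coupling.n_normals)]

    baseline = 100.0 * np.exp(rng.normal(0.0, 0.8, n_genes))
    coupled = rng.random(n_genes) < coupling.coupled_fraction
    is_up = rng.random(n_genes) < coupling.frac_up
    is_down = (~is_up) & (rng.random(n_genes) < coupling.frac_down)

    factor = np.ones((n_genes, len(tumours)))
    for ti, t in enumerate(tumours):
        hit = rng.random(n_genes) < coupling.change_prob
        factor[is_up & hit, ti] *= coupling.fold_up
        factor[is_down & hit, ti] *= coupling.fold_down
        if true_genecn is not None:
            r = true_genecn.ratios[t].reindex(genes).to_numpy()
            r = np.nan_to_num(r, nan=0.0)
            factor[coupled, ti] *= 2.0 ** r[coupled]

    truth = np.full((n_genes, len(tumours)), "NC", dtype=object)
    truth[factor > 2.0] = "UP"
    truth[factor < 0.5] = "DOWN"

    ln2 = math.log(2.0)
    signals = {}
    for j, s in enumerate(normals):
        noise = np.exp(rng.normal(0.0, coupling.expr_noise_sd * ln2, n_genes))
        signals[s] = baseline * noise
    for ti, t in enumerate(tumours):
        noise = np.exp(rng.normal(0.0, coupling.expr_noise_sd * ln2, n_genes))
        signals[t] = baseline * factor[:, ti] * noise
    sig = pd.DataFrame(signals, index=genes)

    calls = pd.DataFrame("P", index=genes, columns=sig.columns)
    low = sig < DETECTION_FLOOR
    drop = pd.DataFrame(
        rng.random(sig.shape) < coupling.detection_dropout,
        index=genes,
        columns=sig.columns,
    )
    calls = calls.mask(low & drop, "A")

    expr = ExpressionMatrix(
        signals=sig, calls=calls, tumours=list(tumours), normals=normals
    )
    truth_df = pd.DataFrame(truth, index=genes, columns=tumours)
    return expr, truth_df


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr_plate(
    true_copies: dict,
    slope: float = -3.3219,
    intercept: float = 40.0,
    ct_sd: float = 0.0,
    seed: int = 0,
    reference: str = "CYP7A1",
) -> pd.DataFrame:
    """Simulate a qPCR plate: calibrator dilutions plus duplicate wells.

    ``true_copies`` maps (sample, target) -> copies loaded in the well.
    Ct = intercept + slope * log10(copies) + N(0, ct_sd).  Each target gets
    a calibrator series at 10..1e5 copies; every sample-target combination
    is run in duplicate.  The ``reference`` argument is only recorded so a
    caller can find the normalisation target later.
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    rng = np.random.default_rng(_child_seeds(seed)[3])
    rows = []
    targets = sorted({t for (_, t) in true_copies})
    for target in targets:
        for copies in CALIBRATOR_COPIES:
            for rep in (1, 2):
                ct = intercept + slope * math.log10(copies) + rng.normal(0, ct_sd)
                rows.append(("calibrator", target, rep, float(ct), copies))
    for (sample, target), copies in true_copies.items():
        if copies <= 0:
            raise ValueError(
                f"non-positive copies for {sample}/{target}: {copies}"
            )
        for rep in (1, 2):
            ct = intercept + slope * math.log10(copies) + rng.normal(0, ct_sd)
            rows.append((sample, target, rep, float(ct), np.nan))
    plate = pd.DataFrame(
        rows, columns=["sample", "target", "replicate", "Ct", "calibrator_copies"]
    )
    plate.attrs["reference"] = reference
    return plate
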