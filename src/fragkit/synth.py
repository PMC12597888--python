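"""Deterministic generators for reference sequences, fragment files, and
two-cohort feature matrices.

The generators emulate the statistical structure cfDNA fragmentation features
assume: a fragment length mixture with a 167 bp nucleosomal mode (sd 10 bp)
and an optional sub-nucleosomal comb of peaks spaced 10.4 bp apart below
150 bp with geometrically decaying weights; nucleosome-phased fragment
placement around planted centers; optional sequence-dependent end-motif bias
and GC-dependent sampling; and two-cohort interval-level MDS effects. Every
output is fully determined by the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from fragkit.fragio import Fragment, GenomicInterval, write_fragfile
from fragkit.mlpipe import FeatureMatrix

__all__ = [
    "LengthModel", "simulate_reference", "simulate_fragments",
    "simulate_cohort", "fragments_to_bam", "draw_lengths",
]

#: nucleosomal mode of the cfDNA fragment length distribution (bp)
MODAL_LENGTH = 167
#: spacing of the sub-nucleosomal oligonucleosome ladder (bp)
COMB_SPACING = 10.4


@dataclass
class LengthModel:
    """Mixture of a Gaussian nucleosomal mode and an optional short-fragment comb.

    The comb places narrow peaks at round(mode - spacing * j) for j in
    [2, 8] (all below 150 bp for the default mode), weighted geometrically
    with ratio ``comb_decay``; ``comb_weight`` is the total probability mass
    of the comb. Drawn lengths are clamped to >= 30 bp.
    """

    mean: float = MODAL_LENGTH
    sd: float = 10.0
    comb: bool = False
    comb_weight: float = 0.25
    comb_decay: float = 0.7
    comb_spacing: float = COMB_SPACING
    comb_peak_sd: float = 1.0

    def peak_positions(self) -> list[int]:
        return [int(round(self.mean - self.comb_spacing * j)) for j in range(2, 9)]


def draw_lengths(model: LengthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n fragment lengths from the mixture, clamped to >= 30 bp."""
    main = np.rint(rng.normal(model.mean, model.sd, size=n)).astype(np.int64)
    if not model.comb:
        return np.maximum(main, 30)
    peaks = np.array(model.peak_positions())
    weights = model.comb_decay ** np.arange(len(peaks))
    weights /= weights.sum()
    use_comb = rng.random(n) < model.comb_weight
    k = int(use_comb.sum())
    if k:
        which = rng.choice(len(peaks), size=k, p=weights)
        comb_lengths = np.rint(
            peaks[which] + rng.normal(0, model.comb_peak_sd, size=k)
        ).astype(np.int64)
        main[use_comb] = comb_lengths
    return np.maximum(main, 30)


def simulate_reference(
    contig_lengths: dict[str, int],
    seed: int,
    out_fasta: str | Path,
    planted_motif: Optional[str] = None,
    motif_positions: Optional[dict[str, Sequence[int]]] = None,
    line_width: int = 70,
) -> Path:
    """Write a uniform-ACGT reference FASTA (+ .fai index), deterministically.

    A motif can be planted at given positions per contig; a BED of planted
    sites is written alongside (``<out>.sites.bed``) when requested.
    """
    from pyfaidx import Faidx

    rng = np.random.default_rng(seed)
    out_fasta = Path(out_fasta)
    bases = np.array(list("ACGT"))
    sites: list[tuple[str, int, int]] = []
    with open(out_fasta, "w") as fh:
        for contig, length in contig_lengths.items():
            if length < 1000:
                raise ValueError("contig lengths must be >= 1 kb")
            seq = rng.choice(bases, size=length)
            if planted_motif and motif_positions and contig in motif_positions:
                motif = np.array(list(planted_motif))
                for pos in motif_positions[contig]:
                    seq[pos : pos + len(motif)] = motif
                    sites.append((contig, pos, pos + len(motif)))
            fh.write(f">{contig}\n")
            s = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(s[i : i + line_width] + "\n")
    Faidx(str(out_fasta))
    if sites:
        with open(str(out_fasta) + ".sites.bed", "w") as fh:
            for contig, s, e in sites:
                fh.write(f"{contig}\t{s}\t{e}\n")
    return out_fasta


def _sample_midpoints(
    n: int,
    contig_length: int,
    rng: np.random.Generator,
    nucleosome_centers: Optional[Sequence[int]],
    placement_sd: float,
) -> np.ndarray:
    if nucleosome_centers is None:
        return rng.integers(0, contig_length, size=n)
    centers = np.asarray(nucleosome_centers)
    which = rng.integers(0, len(centers), size=n)
    mids = np.rint(centers[which] + rng.normal(0, placement_sd, size=n)).astype(np.int64)
    return np.clip(mids, 0, contig_length - 1)


def simulate_fragments(
    n_fragments: int,
    contig_lengths: dict[str, int],
    seed: int,
    out: Optional[str | Path] = None,
    length_model: Optional[LengthModel] = None,
    nucleosome_centers: Optional[dict[str, Sequence[int]]] = None,
    placement_sd: float = 20.0,
    reference: Optional[str | Path] = None,
    gc_bias: Optional[float] = None,
    dirty: bool = False,
    dirty_fraction: float = 0.1,
) -> list[Fragment]:
    """Draw fragments; optionally write a sorted, indexed frag.gz.

    Midpoints are placed uniformly, or normally around ``nucleosome_centers``
    (sd ``placement_sd``) when given. Lengths follow ``length_model``;
    strand is Bernoulli(1/2); mapq is fixed at 60 so default filters are
    pass-through. ``gc_bias`` (in [0, 1]) thins fragments with local-GC-
    dependent keep probability 1 - gc_bias * gc (requires ``reference``).
    ``dirty`` additionally injects a fraction of low-mapq records and exact
    duplicates to exercise filters.
    """
    rng = np.random.default_rng(seed)
    model = length_model or LengthModel()
    contigs = list(contig_lengths)
    weights = np.array([contig_lengths[c] for c in contigs], dtype=float)
    weights /= weights.sum()
    seqs: dict[str, str] = {}
    if gc_bias is not None:
        if reference is None:
            raise ValueError("gc_bias requires a reference")
        from pyfaidx import Fasta

        fa = Fasta(str(reference))
        seqs = {c: str(fa[c][:]).upper() for c in contigs}

    frags: list[Fragment] = []
    batch = max(n_fragments, 1000)
    while len(frags) < n_fragments:
        which = rng.choice(len(contigs), size=batch, p=weights)
        for ci in which:
            if len(frags) >= n_fragments:
                break
            contig = contigs[ci]
            clen = contig_lengths[contig]
            centers = nucleosome_centers.get(contig) if nucleosome_centers else None
            mid = int(_sample_midpoints(1, clen, rng, centers, placement_sd)[0])
            length = int(draw_lengths(model, 1, rng)[0])
            start = mid - length // 2
            end = start + length
            if start < 0 or end > clen:
                continue
            if gc_bias is not None:
                seq = seqs[contig][start:end]
                gc = (seq.count("G") + seq.count("C")) / max(len(seq), 1)
                if rng.random() > 1.0 - gc_bias * gc:
                    continue
            strand = "+" if rng.random() < 0.5 else "-"
            frags.append(Fragment(contig, start, end, 60, strand))

    if dirty:
        n_bad = int(round(dirty_fraction * len(frags)))
        idx = rng.choice(len(frags), size=n_bad, replace=False)
        extra: list[Fragment] = []
        for j in idx:
            f = frags[j]
            if rng.random() < 0.5:  # low-mapq record
                extra.append(Fragment(f.contig, f.start, f.end, 5, f.strand))
            else:  # exact duplicate
                extra.append(f)
        frags.extend(extra)

    if out is not None:
        write_fragfile(frags, out, contig_order=contigs)
    return frags


def fragments_to_bam(
    fragments: Sequence[Fragment],
    contig_lengths: dict[str, int],
    out: str | Path,
    read_length: int = 60,
) -> Path:
    """Encode fragments as a coordinate-sorted, indexed BAM of proper pairs.

    Each fragment becomes one properly-paired read pair: read 1 on the
    fragment's strand, both mates carrying the fragment's mapq, template
    length equal to the fragment length. Used for dialect-equivalence tests
    between BAM and frag.gz inputs.
    """
    out = Path(out)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(contig_lengths)}
    unsorted = str(out) + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for i, f in enumerate(fragments):
            rlen = min(read_length, f.length)
            left = pysam.AlignedSegment()
            right = pysam.AlignedSegment()
            for seg in (left, right):
                seg.query_name = f"frag{i}"
                seg.reference_id = tid[f.contig]
                seg.next_reference_id = tid[f.contig]
                seg.mapping_quality = f.mapq
                seg.query_sequence = "A" * rlen
                seg.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                seg.cigartuples = [(0, rlen)]
            left.reference_start = f.start
            right.reference_start = f.end - rlen
            left.next_reference_start = right.reference_start
            right.next_reference_start = left.reference_start
            left.template_length = f.length
            right.template_length = -f.length
            # FR orientation: left mate forward, right mate reverse;
            # read 1 is the mate on the fragment's strand
            left.flag |= 0x1 | 0x2 | 0x20
            right.flag |= 0x1 | 0x2 | 0x10
            r1, r2 = (left, right) if f.strand != "-" else (right, left)
            r1.flag |= 0x40
            r2.flag |= 0x80
            bam.write(left)
            bam.write(right)
    pysam.sort("-o", str(out), unsorted)
    os.remove(unsorted)
    pysam.index(str(out))
    return out


def simulate_cohort(
    n_per_group: int = 25,
    n_intervals: int = 500,
    effect_intervals: Optional[Sequence[int]] = None,
    effect_size: float = 0.05,
    noise_sd: float = 0.01,
    baseline: float = 0.95,
    seed: int = 0,
) -> FeatureMatrix:
    """Two-cohort interval-MDS feature matrix with a planted case effect.

    Control MDS values are baseline + Gaussian noise; case values are shifted
    by -effect_size in ``effect_intervals`` only (default: the first 100).
    Values are clipped to [0, 1]; labels are balanced (0 = control,
    1 = case).
    """
    rng = np.random.default_rng(seed)
    if effect_intervals is None:
        effect_intervals = range(min(100, n_intervals))
    effect_idx = np.asarray(list(effect_intervals), dtype=int)
    if effect_idx.size and (effect_idx.min() < 0 or effect_idx.max() >= n_intervals):
        raise ValueError("effect_intervals out of range")
    n = 2 * n_per_group
    values = baseline + rng.normal(0, noise_sd, size=(n, n_intervals))
    labels = np.array([0] * n_per_group + [1] * n_per_group)
    if effect_idx.size:
        values[n_per_group:, effect_idx] -= effect_size
    values = np.clip(values, 0.0, 1.0)
    features = [f"iv{i}" for i in range(n_intervals)]
    samples = [f"ctrl{i}" for i in range(n_per_group)] + [
        f"case{i}" for i in range(n_per_group)
    ]
    return FeatureMatrix(samples, features, values, labels)
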