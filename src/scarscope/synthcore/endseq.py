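"""Generate strand-resolved end-count tracks decaying away from cut sites.

For each site, ``reads_per_site`` resection endpoints are drawn per side with
distance ~ Exponential(mean_resection_bp) (or Gamma) and deposited as
single-base end counts moving outward from the site center; a uniform Poisson
background is added genome-wide. The truth table stores each site's true mean
resection length.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .._rng import substream
from .params import EndSeqSimParams

__all__ = ["gen_endseq_track", "gen_genome"]

MOTIF = "GCGATCGC"
_CENTER_OFFSET = 4  # site center = motif start + half the 8-bp motif


def _chrom_lengths(genome: Mapping[str, str] | Mapping[str, int]) -> dict[str, int]:
    return {c: (v if isinstance(v, int) else len(v)) for c, v in genome.items()}


def gen_endseq_track(
    genome: Mapping[str, str] | Mapping[str, int],
    params: EndSeqSimParams,
) -> tuple[dict[str, np.ndarray] | dict[str, dict[str, np.ndarray]], pd.DataFrame]:
    """Return ``(coverage, truth)``.

    ``coverage`` maps chrom -> per-base end-count array, or (with
    ``strand_model``) chrom -> {"+": array, "-": array} where minus-strand
    ends fall left of the site and plus-strand ends right of it. Endpoints
    beyond a contig edge are truncated to the edge (with a warning).
    """
    lengths = _chrom_lengths(genome)
    for chrom, positions in params.sites.items():
        if chrom not in lengths:
            raise ValueError(f"site chrom {chrom!r} absent from genome")
        for pos in positions:
            if not 0 <= pos < lengths[chrom]:
                raise ValueError(f"site {chrom}:{pos} outside genome bounds")

    rng = substream(params.seed, "endseq_track")
    minus = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
    plus = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}

    rows = []
    for chrom in sorted(params.sites):
        n_chrom = lengths[chrom]
        for pos in sorted(params.sites[chrom]):
            center = pos + _CENTER_OFFSET
            mean = params.mean_for(chrom, pos)
            if center < mean or n_chrom - center < mean:
                warnings.warn(
                    f"site {chrom}:{pos} is within mean_resection_bp of a contig "
                    "edge; endpoints truncated", stacklevel=2,
                )
            for side, track in (("-", minus), ("+", plus)):
                if params.endpoint_dist == "gamma":
                    dist = rng.gamma(params.gamma_shape, mean / params.gamma_shape,
                                     size=params.reads_per_site)
                else:
                    dist = rng.exponential(mean, size=params.reads_per_site)
                offsets = np.ceil(dist).astype(int)
                if side == "-":
                    ends = np.clip(center - offsets, 0, n_chrom - 1)
                else:
                    ends = np.clip(center + offsets, 0, n_chrom - 1)
                np.add.at(track[chrom], ends, 1.0)
            rows.append({"chrom": chrom, "pos": pos, "center": center,
                         "true_mean_bp": mean, "reads_per_side": params.reads_per_site})

    if params.background_rate > 0:
        per_base = params.background_rate / 1000.0
        for chrom, n_chrom in lengths.items():
            for track in (minus, plus):
                n_bg = rng.poisson(per_base * n_chrom / 2.0)
                if n_bg:
                    bg_pos = rng.integers(0, n_chrom, size=n_bg)
                    np.add.at(track[chrom], bg_pos, 1.0)

    truth = pd.DataFrame(rows, columns=["chrom", "pos", "center", "true_mean_bp", "reads_per_side"])
    if params.strand_model:
        coverage = {c: {"+": plus[c], "-": minus[c]} for c in lengths}
        return coverage, truth
    combined = {c: plus[c] + minus[c] for c in lengths}
    return combined, truth


def gen_genome(
    chrom_lengths: Mapping[str, int],
    motif_positions: Mapping[str, list[int]] | None = None,
    seed: int = 0,
    motif: str = MOTIF,
) -> dict[str, str]:
    """Random genome with the motif planted only at the requested positions.

    Spurious occurrences of ``motif`` arising by chance are scrubbed (one base
    rotated) before planting, so motif scans return exactly the planted set.
    """
    rng = substream(seed, "genome")
    motif_positions = motif_positions or {}
    genome: dict[str, str] = {}
    for chrom, n in chrom_lengths.items():
        arr = rng.choice(list("ACGT"), size=n)
        seq = "".join(arr)
        # scrub chance occurrences (also re-check after each substitution)
        start = seq.find(motif)
        while start != -1:
            base = seq[start + 4]
            repl = "A" if base != "A" else "C"
            seq = seq[:start + 4] + repl + seq[start + 5:]
            start = seq.find(motif)
        wanted = sorted(motif_positions.get(chrom, []))
        for pos in wanted:
            if not 0 <= pos <= n - len(motif):
                raise ValueError(f"motif position {chrom}:{pos} does not fit the contig")
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        found, start = [], seq.find(motif)
        while start != -1:
            found.append(start)
            start = seq.find(motif, start + 1)
        if found != wanted:
            raise ValueError(
                f"planting motifs on {chrom} produced unexpected occurrences "
                f"(wanted {wanted}, found {found}); adjust positions or seed"
            )
        genome[chrom] = seq
    return genome
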