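"""Render nuclei as bright disks with Gaussian foci, plus per-nucleus truth.

Nuclei are laid out on a jittered grid so they can never overlap; foci are
placed inside each nucleus with a minimum mutual separation and rendered as
2D Gaussian spots. Noise, when requested, is Poisson on intensity.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .._rng import substream
from .params import draw_sizes

__all__ = ["gen_foci_images"]

_MAX_TRIES = 5000


def gen_foci_images(
    n_nuclei: int,
    foci_count_dist: Mapping,
    spot_sigma_px: float = 1.5,
    noise_model: str = "none",
    seed: int = 0,
    *,
    nucleus_radius_px: int = 24,
    nucleus_intensity: float = 300.0,
    focus_amplitude: float = 1200.0,
    background_intensity: float = 20.0,
    min_separation_px: float | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Return ``(image, nucleus_labels, truth)``.

    ``image`` is a single-channel uint16 array; ``nucleus_labels`` is an
    integer label map (0 = background, nuclei labeled 1..n); ``truth`` has one
    row per nucleus with its true focus count. Raises if the requested focus
    density cannot fit inside a nucleus at the minimum spot separation.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if spot_sigma_px <= 0:
        raise ValueError("spot_sigma_px must be > 0")
    if noise_model not in ("none", "poisson"):
        raise ValueError("noise_model must be 'none' or 'poisson'")
    if min_separation_px is None:
        min_separation_px = 6.0 * spot_sigma_px

    rng = substream(seed, "foci_images")
    margin = max(8, int(math.ceil(4 * spot_sigma_px)))
    cell = 2 * nucleus_radius_px + 2 * margin
    cols = max(1, int(math.ceil(math.sqrt(max(n_nuclei, 1)))))
    rows = max(1, int(math.ceil(max(n_nuclei, 1) / cols)))
    shape = (rows * cell, cols * cell)

    image = np.full(shape, background_intensity, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]

    # capacity of the spot-placement disk at the minimum separation
    place_radius = nucleus_radius_px - 3.0 * spot_sigma_px
    if place_radius <= 0:
        raise ValueError("nucleus too small for the requested spot size")
    capacity = int(math.pi * place_radius**2 / (min_separation_px**2))

    counts = draw_sizes(rng, foci_count_dist, n_nuclei) if n_nuclei else np.array([], dtype=int)
    rows_out = []
    for i in range(n_nuclei):
        r, c = divmod(i, cols)
        jitter = rng.integers(-margin // 2, margin // 2 + 1, size=2)
        cy = r * cell + cell // 2 + int(jitter[0])
        cx = c * cell + cell // 2 + int(jitter[1])

        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius_px**2
        image[disk] = nucleus_intensity
        labels[disk] = i + 1

        k = int(counts[i])
        if k > max(capacity, 1):
            raise ValueError(
                f"{k} foci exceed nucleus capacity (~{capacity}) at minimum "
                f"separation {min_separation_px:.1f} px"
            )
        centers: list[tuple[float, float]] = []
        tries = 0
        while len(centers) < k:
            tries += 1
            if tries > _MAX_TRIES:
                raise ValueError("could not place foci at the requested separation")
            ang = rng.uniform(0, 2 * math.pi)
            rad = place_radius * math.sqrt(rng.uniform())
            fy, fx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
            if all((fy - y0) ** 2 + (fx - x0) ** 2 >= min_separation_px**2
                   for y0, x0 in centers):
                centers.append((fy, fx))

        half = int(math.ceil(5 * spot_sigma_px))
        for fy, fx in centers:
            y0, y1 = int(fy) - half, int(fy) + half + 1
            x0, x1 = int(fx) - half, int(fx) + half + 1
            py, px = np.mgrid[y0:y1, x0:x1]
            spot = focus_amplitude * np.exp(
                -((py - fy) ** 2 + (px - fx) ** 2) / (2 * spot_sigma_px**2)
            )
            image[y0:y1, x0:x1] += spot

        rows_out.append({"nucleus_id": i + 1, "center_y": cy, "center_x": cx, "n_foci": k})

    if noise_model == "poisson":
        image = rng.poisson(image).astype(float)
    image = np.clip(np.rint(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    truth = pd.DataFrame(rows_out, columns=["nucleus_id", "center_y", "center_x", "n_foci"])
    return image, labels, truth
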