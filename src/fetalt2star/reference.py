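"""Normative reference values for regional fetal brain T2* at 0.55 T.

Per-region T2* summary statistics (mean, 5th/50th/95th percentile, ms) for
2-week gestational-age bins from 20 to 40 weeks, measured in 92 control
fetal scans. The bins are half-open ``[a, a+2)`` weeks; the last bin is
closed at 40 weeks. These values parameterize the digital phantom and the
synthetic control cohorts.
"""

from __future__ import annotations

import numpy as np

#: The seven merged anatomical categories, in label order 1..7.
REGIONS = (
    "eCSF",
    "gray_matter",
    "white_matter",
    "deep_gray_matter",
    "ventricles",
    "cerebellum",
    "brainstem",
)

#: label value of each merged region in a merged LabelVolume (0 = background)
REGION_LABELS = {name: i + 1 for i, name in enumerate(REGIONS)}

#: GA bin edges in weeks: [20,22), [22,24), ..., [38,40] (last bin closed).
BIN_EDGES = np.arange(20.0, 42.0, 2.0)

#: midpoints of the GA bins, weeks
BIN_MIDPOINTS = (BIN_EDGES[:-1] + BIN_EDGES[1:]) / 2.0

#: number of control scans per GA bin (sums to 92)
BIN_N = np.array([8, 10, 11, 9, 9, 8, 11, 8, 7, 11])

# Per region: "mean", "p5", "p50", "p95" — one value per GA bin, in ms.
REFERENCE_T2STAR = {
    "eCSF": {
        "mean": [357.7, 362.8, 365.9, 370.4, 358.9, 357.5, 331.4, 307.7, 266.4, 228.9],
        "p5":   [328.3, 337.0, 336.4, 341.9, 309.3, 328.9, 298.8, 276.6, 217.3, 198.7],
        "p50":  [354.1, 356.1, 371.8, 374.2, 352.5, 357.1, 333.5, 302.0, 280.9, 230.7],
        "p95":  [394.3, 392.4, 386.7, 399.1, 413.2, 383.4, 358.5, 339.6, 299.3, 264.0],
    },
    "gray_matter": {
        "mean": [294.4, 272.9, 266.9, 258.2, 259.0, 254.1, 233.6, 225.0, 201.3, 178.1],
        "p5":   [266.8, 250.1, 242.1, 232.4, 225.9, 228.1, 214.9, 200.4, 180.3, 157.7],
        "p50":  [290.3, 264.5, 261.0, 261.7, 260.1, 246.0, 235.7, 226.9, 196.4, 179.4],
        "p95":  [328.7, 316.6, 289.0, 286.5, 295.1, 288.1, 250.6, 243.0, 231.0, 201.7],
    },
    "white_matter": {
        "mean": [311.7, 320.5, 321.6, 331.6, 321.0, 316.9, 289.7, 281.3, 253.0, 221.7],
        "p5":   [293.3, 292.9, 290.0, 308.9, 286.8, 280.6, 264.3, 249.0, 228.9, 203.7],
        "p50":  [317.7, 320.4, 329.5, 341.7, 333.1, 311.5, 294.1, 286.0, 249.6, 219.0],
        "p95":  [323.6, 346.1, 340.2, 343.6, 346.7, 359.1, 315.0, 301.8, 290.1, 243.3],
    },
    "ventricles": {
        "mean": [409.0, 402.6, 395.9, 420.6, 391.1, 385.1, 378.5, 369.0, 364.4, 332.9],
        "p5":   [371.8, 379.4, 324.0, 372.8, 364.3, 343.6, 325.8, 347.2, 340.2, 275.8],
        "p50":  [412.3, 398.5, 415.3, 427.5, 390.8, 387.4, 380.5, 358.1, 358.0, 336.9],
        "p95":  [438.3, 429.7, 436.5, 453.2, 412.1, 418.1, 416.3, 402.7, 397.7, 372.1],
    },
    "brainstem": {
        "mean": [243.0, 236.7, 225.6, 222.3, 210.0, 199.6, 189.2, 177.6, 168.7, 149.6],
        "p5":   [227.2, 221.7, 217.9, 211.7, 175.5, 187.7, 176.3, 163.9, 145.4, 135.6],
        "p50":  [241.2, 236.1, 223.3, 222.0, 215.0, 196.8, 184.3, 177.7, 165.1, 148.3],
        "p95":  [267.8, 252.2, 238.7, 237.2, 229.3, 220.1, 205.5, 188.9, 202.4, 160.0],
    },
    "cerebellum": {
        "mean": [315.8, 337.4, 325.4, 315.9, 297.6, 288.0, 253.7, 243.8, 214.5, 178.2],
        "p5":   [289.7, 297.9, 309.6, 290.1, 259.7, 264.6, 223.2, 219.7, 172.4, 151.2],
        "p50":  [319.7, 344.3, 319.9, 321.9, 297.7, 286.1, 254.7, 244.5, 210.4, 181.8],
        "p95":  [335.6, 371.9, 346.1, 332.2, 322.5, 312.3, 281.0, 266.0, 249.0, 194.4],
    },
    "deep_gray_matter": {
        "mean": [223.2, 251.2, 242.3, 243.4, 230.9, 221.6, 211.0, 198.4, 184.8, 167.9],
        "p5":   [150.4, 223.6, 221.9, 232.2, 213.5, 198.4, 196.7, 188.4, 172.7, 154.0],
        "p50":  [242.4, 249.7, 247.0, 246.9, 234.3, 225.1, 213.9, 199.2, 176.1, 165.7],
        "p95":  [262.1, 275.3, 256.0, 248.8, 245.1, 247.3, 225.1, 208.5, 208.7, 185.9],
    },
}

#: per-region proton-density-like signal amplitude S0 (arbitrary units);
#: fluid compartments brightest, background zero.
DEFAULT_S0 = {
    "eCSF": 1000.0,
    "gray_matter": 850.0,
    "white_matter": 800.0,
    "deep_gray_matter": 820.0,
    "ventricles": 1000.0,
    "cerebellum": 830.0,
    "brainstem": 810.0,
}


def ga_bin_index(ga: float) -> int:
    """Index of the 2-week GA bin containing ``ga`` (last bin closed at 40)."""
    if not (20.0 <= ga <= 40.0):
        raise ValueError(f"gestational age {ga} outside the reference range [20, 40] weeks")
    return min(int((ga - 20.0) // 2.0), len(BIN_N) - 1)


def lookup_reference_t2star(region: str, ga: float, statistic: str = "mean") -> float:
    """Reference T2* (ms) for ``region`` at gestational age ``ga`` weeks.

    Piecewise-linear interpolation of the per-bin values placed at bin
    midpoints (21, 23, ..., 39 weeks), with constant extrapolation beyond
    the outermost midpoints. ``ga`` must lie in [20, 40].
    """
    if region not in REFERENCE_T2STAR:
        raise KeyError(f"unknown region {region!r}; expected one of {REGIONS}")
    if not (20.0 <= ga <= 40.0):
        raise ValueError(f"gestational age {ga} outside the reference range [20, 40] weeks")
    vals = np.asarray(REFERENCE_T2STAR[region][statistic], dtype=float)
    # np.interp clamps outside the knot range = constant extrapolation
    return float(np.interp(ga, BIN_MIDPOINTS, vals))


def reference_sd(region: str, ga: float) -> float:
    """Gaussian spread implied by the bin's 5th-95th percentile span.

    For a normal distribution the 5th-95th span is 2 * 1.645 sigma = 3.29
    sigma, so sigma = (p95 - p5) / 3.29 for the bin containing ``ga``.
    """
    i = ga_bin_index(ga)
    ref = REFERENCE_T2STAR[region]
    return (ref["p95"][i] - ref["p5"][i]) / 3.29
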