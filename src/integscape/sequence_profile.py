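"""Flanking-window extraction, aggregated target-site matrices, and
dinucleotide step-parameter ("DNA flexibility") profiles.

Windows are 48 nt, oriented along the insertion strand. Two layouts:

* ``transposon_tsd`` — 20 nt before and after the 8-bp target-site
  duplication of hAT-family transposons (Ds, Tol2): positions 21-28 (1-based)
  are the duplicated site;
* ``point_integration`` — 20 nt before and 28 nt after a point insertion
  (retroviruses and the mouse-style transposon sets), so that position 21 is
  the first base of the integration site.

Each window reduces to its 47 overlapping dinucleotide steps; every step is
assigned mean rigid-body parameters (Twist, Tilt, Roll in degrees; Shift,
Slide, Rise in angstroms) from the crystallographic compilation of
protein-DNA complexes, and the per-position mean over all windows is the
flexibility profile. Step labels here follow the convention in which a GC
step has 36.1 deg Twist and 0.41 A Slide and a GG step 32.9 deg and
-0.22 A (the reversed-dinucleotide labelling of the source compilation;
reverse-complement symmetry of the table is unaffected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_core import (
    Genome,
    GenomicInterval,
    IntegrationSite,
    extract_window,
    reverse_complement,
)

PARAMETERS = ("Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")
LAYOUTS = ("transposon_tsd", "point_integration")
BASES = "ACGT"
STEPS = tuple(a + b for a in BASES for b in BASES)

# Mean dinucleotide step parameters from protein-DNA crystal complexes
# (Twist/Tilt/Roll in degrees, Shift/Slide/Rise in angstroms).
#                Twist  Tilt  Roll  Shift  Slide  Rise
_STEP_ROWS = {
    "AA": (35.1, -1.4, 0.7, -0.03, -0.08, 3.27),
    "AC": (37.3, -0.5, 4.7, 0.09, 0.53, 3.33),
    "AG": (36.3, -1.5, 1.9, -0.28, 0.09, 3.37),
    "AT": (37.8, 0.0, 3.3, 0.00, 0.05, 3.42),
    "CA": (31.5, -0.1, 0.7, 0.13, -0.58, 3.36),
    "CC": (32.9, 0.1, 3.6, 0.05, -0.22, 3.42),
    "CG": (33.6, 0.0, 0.3, 0.00, -0.38, 3.40),
    "CT": (36.3, 1.5, 1.9, 0.28, 0.09, 3.37),
    "GA": (31.9, -1.7, 4.5, 0.09, -0.25, 3.34),
    "GC": (36.1, 0.0, 5.4, 0.00, 0.41, 3.39),
    "GG": (32.9, -0.1, 3.6, -0.05, -0.22, 3.42),
    "GT": (37.3, 0.5, 4.7, -0.09, 0.53, 3.33),
    "TA": (29.3, 0.0, 1.1, 0.00, -0.59, 3.31),
    "TC": (31.9, 1.7, 4.5, -0.09, -0.25, 3.34),
    "TG": (31.5, 0.1, 0.7, -0.13, -0.58, 3.36),
    "TT": (35.1, 1.4, 0.7, 0.03, -0.08, 3.27),
}


@dataclass(frozen=True)
class StepParameterTable:
    """Mean step values for all 16 dinucleotide steps x 6 parameters."""

    values: dict[str, dict[str, float]]  # parameter -> step -> value

    def value(self, parameter: str, step: str) -> float:
        return self.values[parameter][step]

    def param_vector(self, parameter: str) -> np.ndarray:
        """Length-16 lookup vector indexed by 4*code(first) + code(second)."""
        return np.array(
            [self.values[parameter][s] for s in STEPS], dtype=np.float64
        )

    def check_symmetry(self) -> None:
        """Reverse-complement symmetry: Twist/Roll/Rise/Slide invariant,
        Tilt/Shift sign-flipped."""
        for step in STEPS:
            rc = reverse_complement(step)
            for p in ("Twist", "Roll", "Rise", "Slide"):
                assert math.isclose(self.values[p][step], self.values[p][rc]), (p, step)
            for p in ("Tilt", "Shift"):
                assert math.isclose(self.values[p][step], -self.values[p][rc]), (p, step)


def step_table() -> StepParameterTable:
    """The vendored crystallographic step-parameter table."""
    values = {
        p: {step: _STEP_ROWS[step][i] for step in STEPS}
        for i, p in enumerate(PARAMETERS)
    }
    return StepParameterTable(values)


_TABLE = step_table()
_TABLE.check_symmetry()
# pinned published anchor values for the labelling convention used here
assert _TABLE.value("Twist", "GC") == 36.1
assert _TABLE.value("Slide", "GC") == 0.41
assert _TABLE.value("Twist", "GG") == 32.9
assert _TABLE.value("Slide", "GG") == -0.22


# ---------------------------------------------------------------------------
# Window extraction


@dataclass
class FlankWindowSet:
    """Equal-length oriented flanking windows with an exclusion tally."""

    windows: list[str]
    layout: str
    n_excluded: int = 0

    def __post_init__(self):
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        lengths = {len(w) for w in self.windows}
        if len(lengths) > 1:
            raise ValueError("windows must all have the same length")

    @property
    def window_length(self) -> int:
        return len(self.windows[0]) if self.windows else 0


def _window_coords(site: IntegrationSite, layout: str, flank: int = 20,
                   after: int = 28) -> tuple[str, int, int, str]:
    """Raw (possibly out-of-bounds) window coordinates for one site."""
    loc = site.location
    if layout == "transposon_tsd":
        if len(loc) != 8:
            raise ValueError(
                f"transposon_tsd layout requires 8-bp TSD intervals, got "
                f"length {len(loc)} at {loc.chrom}:{loc.start}"
            )
        return loc.chrom, loc.start - flank, loc.end + flank, loc.strand
    if len(loc) != 1:
        raise ValueError(
            f"point_integration layout requires 1-bp locations, got length "
            f"{len(loc)} at {loc.chrom}:{loc.start}"
        )
    p = loc.start
    if loc.strand == "+":
        return loc.chrom, p - flank, p + after, "+"
    return loc.chrom, p - after + 1, p + flank + 1, "-"


def extract_flank_windows(
    sites: list[IntegrationSite], genome: Genome, layout: str
) -> FlankWindowSet:
    """48-nt oriented windows around each site; N-containing or out-of-bounds
    windows are excluded and tallied."""
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    windows = []
    n_excluded = 0
    for site in sites:
        chrom, start, end, strand = _window_coords(site, layout)
        if start < 0 or end > genome.lengths.get(chrom, 0):
            n_excluded += 1
            continue
        seq = extract_window(genome, GenomicInterval(chrom, start, end, strand))
        if "N" in seq:
            n_excluded += 1
            continue
        windows.append(seq)
    return FlankWindowSet(windows=windows, layout=layout, n_excluded=n_excluded)


def control_flank_windows(
    control_sets, genome: Genome, layout: str, vector: str = "control"
) -> list[FlankWindowSet]:
    """Apply the experimental window geometry to replicate control sets.

    Control intervals are treated as insertion points at their start
    coordinate (with an 8-bp pseudo-duplication for the TSD layout); unstranded
    controls are read on the plus strand.
    """
    out = []
    for ctrl in control_sets:
        pseudo = []
        for iv in ctrl:
            strand = iv.strand if iv.strand in ("+", "-") else "+"
            length = 8 if layout == "transposon_tsd" else 1
            pseudo.append(
                IntegrationSite(
                    GenomicInterval(iv.chrom, iv.start, iv.start + length, strand),
                    vector=vector, fragment_count=0, method="NGS",
                )
            )
        out.append(extract_flank_windows(pseudo, genome, layout))
    return out


# ---------------------------------------------------------------------------
# Position matrices

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


def encode_windows(windows: list[str]) -> np.ndarray:
    """(n_windows, L) int8 base codes; raises on non-ACGT characters."""
    if not windows:
        raise ValueError("empty window set")
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[arr].reshape(len(windows), len(windows[0]))
    if (codes < 0).any():
        raise ValueError("windows contain non-ACGT characters")
    return codes


@dataclass
class PositionMatrix:
    """Per-position base probabilities and information content."""

    probs: pd.DataFrame  # index: 1-based position, columns A,C,G,T
    bits: np.ndarray

    def __post_init__(self):
        assert np.allclose(self.probs.sum(axis=1), 1.0)


def position_matrix(
    windows: FlankWindowSet, small_sample_correction: bool = False
) -> PositionMatrix:
    """Aggregate a window set into a probability matrix with per-position
    information content (uniform background): bits = 2 + sum_b p_b log2 p_b.

    ``small_sample_correction`` subtracts the standard e_n = 3/(2 ln2 n)
    term (floored at 0) for parity with logo tools; off by default so the
    matrix stays a pure function of the frequencies.
    """
    codes = encode_windows(windows.windows)
    n, L = codes.shape
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)], axis=1)
    probs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    bits = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        bits = np.maximum(0.0, bits - 3.0 / (2.0 * math.log(2) * n))
    df = pd.DataFrame(probs, columns=list(BASES),
                      index=pd.RangeIndex(1, L + 1, name="position"))
    return PositionMatrix(probs=df, bits=bits)


# ---------------------------------------------------------------------------
# Flexibility profiles


def window_step_codes(codes: np.ndarray) -> np.ndarray:
    """(n, L-1) dinucleotide step indices (4*first + second)."""
    return 4 * codes[:, :-1] + codes[:, 1:]


def positional_means(
    windows: FlankWindowSet, table: StepParameterTable, parameter: str
) -> np.ndarray:
    """Per-dinucleotide-position mean parameter value over the windows."""
    steps = window_step_codes(encode_windows(windows.windows))
    vec = table.param_vector(parameter)
    return vec[steps].mean(axis=0)


def window_means(
    windows: list[str], table: StepParameterTable, parameter: str
) -> np.ndarray:
    """Per-window mean parameter value (used for flexibility-biased
    simulation and summary statistics)."""
    steps = window_step_codes(encode_windows(windows))
    vec = table.param_vector(parameter)
    return vec[steps].mean(axis=1)


@dataclass
class FlexibilityProfile:
    parameter: str
    values: np.ndarray  # length L-1 experimental per-position means
    control_mean: np.ndarray | None = None
    control_sd: np.ndarray | None = None
    control_profiles: np.ndarray | None = None  # (n_replicates, L-1)

    @property
    def n_positions(self) -> int:
        return len(self.values)


def flexibility_profile(
    windows: FlankWindowSet,
    table: StepParameterTable,
    parameter: str,
    control_window_sets: list[FlankWindowSet] | None = None,
) -> FlexibilityProfile:
    """Experimental flexibility profile with an optional control envelope.

    The envelope applies the identical positional averaging to each replicate
    control window set and records the across-replicate mean and sd.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    values = positional_means(windows, table, parameter)
    ctrl_mean = ctrl_sd = ctrl_profiles = None
    if control_window_sets:
        ctrl_profiles = np.stack(
            [positional_means(c, table, parameter) for c in control_window_sets]
        )
        ctrl_mean = ctrl_profiles.mean(axis=0)
        ctrl_sd = ctrl_profiles.std(axis=0, ddof=1)
    return FlexibilityProfile(
        parameter=parameter, values=values, control_mean=ctrl_mean,
        control_sd=ctrl_sd, control_profiles=ctrl_profiles,
    )


def profile_divergence(profile: FlexibilityProfile, min_replicates: int = 30
                       ) -> pd.DataFrame:
    """Quantify the experimental-vs-control comparison per position.

    Columns: ``z`` = (exp - control_mean) / control_sd (NaN where the control
    sd is 0, flagged in ``sd_zero``), and ``empirical_p`` = fraction of
    control replicates at least as far from the control mean as the
    experimental value.
    """
    if profile.control_profiles is None:
        raise ValueError("profile has no control envelope")
    n_rep = profile.control_profiles.shape[0]
    if n_rep < min_replicates:
        raise ValueError(
            f"need >= {min_replicates} control replicates, got {n_rep}"
        )
    dev = profile.values - profile.control_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(profile.control_sd > 0, dev / profile.control_sd, np.nan)
    ctrl_dev = np.abs(profile.control_profiles - profile.control_mean)
    emp = (ctrl_dev >= np.abs(dev)).mean(axis=0)
    return pd.DataFrame(
        {
            "position": np.arange(1, profile.n_positions + 1),
            "exp": profile.values,
            "ctrl_mean": profile.control_mean,
            "ctrl_sd": profile.control_sd,
            "z": z,
            "empirical_p": emp,
            "sd_zero": profile.control_sd == 0,
        }
    )


def region_divergence(
    profile: FlexibilityProfile,
    start: int | None = None,
    end: int | None = None,
    min_replicates: int = 30,
) -> tuple[float, float]:
    """Aggregate (z, empirical_p) for the mean profile deviation over a
    position slice ``[start, end)`` (0-based; default the central third).

    A window-wide flexibility preference shifts every position by the same
    small amount, so the region mean — standardized against the
    across-replicate scatter of the same region mean — is the powered
    detector; per-position z-scores dilute such a shift by the ratio of
    per-step to window-mean variability.
    """
    if profile.control_profiles is None:
        raise ValueError("profile has no control envelope")
    n_rep, L = profile.control_profiles.shape
    if n_rep < min_replicates:
        raise ValueError(f"need >= {min_replicates} control replicates")
    if start is None or end is None:
        start, end = L // 3, L - L // 3
    exp_mean = profile.values[start:end].mean()
    ctrl_means = profile.control_profiles[:, start:end].mean(axis=1)
    sd = ctrl_means.std(ddof=1)
    if sd == 0:
        return math.nan, math.nan
    z = float((exp_mean - ctrl_means.mean()) / sd)
    emp = float(
        (np.abs(ctrl_means - ctrl_means.mean()) >=
         abs(exp_mean - ctrl_means.mean())).mean()
    )
    return z, emp
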