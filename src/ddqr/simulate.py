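"""Simulation study: compression-rate sweeps over random sequences with a
controlled dominant-base composition, comparator ratio series, and the
sliding-window cutoff detector.

Sequences are drawn with one base (default 'A') given a fixed dominant
proportion; the other three proportions are drawn from a flat Dirichlet on
the remaining probability mass, then positions are sampled independently.
A dominant proportion of 0.25 is the uniform composition; 1.0 is a
single-letter sequence. The compression rate of a sequence depends only on
its base counts, so the sweep computes rates directly from multinomial
count draws — exactly equivalent to building each sequence and encoding it
(asserted in the test suite) but orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .coding import BASES, Profile, ddqr_encode, normalize_sequence, rate_from_counts
from .errors import InsufficientDataError

__all__ = [
    "SimulationSpec",
    "CutoffResult",
    "generate_sequence",
    "generate_composition",
    "simulate_rates",
    "run_sweep",
    "ratio_series",
    "detect_cutoff",
    "ComparatorCompressor",
    "IdentityComparator",
    "TwoBitPackerComparator",
    "DdqrComparator",
    "SubprocessComparator",
    "mean_cutoff",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for a sweep.

    ``dominant_fractions`` spans 0.25 (uniform; below 1/4 a maximum
    frequency is impossible) to 1.0; replicates defaults to the study's 500
    sequences per (length, composition) cell.
    """

    lengths: tuple[int, ...]
    dominant_fractions: tuple[float, ...] = (0.25,)
    dominant_base: str = "A"
    replicates: int = 500
    seed: int = 0

    def __post_init__(self):
        if any(length < 1 for length in self.lengths):
            raise ValueError("lengths must be positive")
        for f in self.dominant_fractions:
            if not 0.25 <= f <= 1.0:
                raise ValueError(
                    f"dominant_fraction must be in [0.25, 1.0], got {f}"
                )
        if self.dominant_base not in BASES:
            raise ValueError(f"dominant_base must be one of {BASES!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")


@dataclass(frozen=True)
class CutoffResult:
    """Detected crossover length of a ratio series (None if never reached)."""

    cutoff_length: float | None
    window: int = 10
    vote_threshold: int = 6


def generate_composition(
    dominant_fraction: float, dominant_base: str, rng: np.random.Generator
) -> dict[str, float]:
    """Base probabilities: fixed dominant share, random minor proportions.

    The three minor proportions are a flat Dirichlet draw on the remaining
    mass, constrained so that none exceeds the dominant fraction (the
    dominant base must stay the most frequent: this is what makes
    dominant_fraction = 0.25 the uniform composition, and it keeps the
    closed-form binary-coding regime exact for fractions up to 0.30). A
    draw violating the cap is shrunk linearly toward the centroid until its
    maximum sits on the cap.
    """
    if not 0.25 <= dominant_fraction <= 1.0:
        raise ValueError("dominant_fraction must be in [0.25, 1.0]")
    rest = rng.dirichlet(np.ones(3)) * (1.0 - dominant_fraction)
    m = (1.0 - dominant_fraction) / 3.0  # centroid component
    peak = rest.max()
    if peak > dominant_fraction:
        t = (dominant_fraction - m) / (peak - m)
        rest = m + t * (rest - m)
    others = [b for b in BASES if b != dominant_base]
    probs = {dominant_base: dominant_fraction}
    probs.update(dict(zip(others, rest)))
    return probs


def generate_sequence(
    length: int,
    dominant_fraction: float,
    dominant_base: str = "A",
    rng: np.random.Generator | None = None,
) -> str:
    """Draw one random sequence under the study's composition model."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    probs = generate_composition(dominant_fraction, dominant_base, rng)
    p = np.array([probs[b] for b in BASES])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def simulate_rates(
    length: int,
    dominant_fraction: float,
    dominant_base: str,
    replicates: int,
    rng: np.random.Generator,
    profile: Profile = Profile.PAPER,
) -> np.ndarray:
    """Compression rates of ``replicates`` random sequences of one cell.

    Drawn via multinomial base counts (distributionally identical to
    sampling each position and counting).
    """
    rates = np.empty(replicates)
    for i in range(replicates):
        probs = generate_composition(dominant_fraction, dominant_base, rng)
        counts = rng.multinomial(length, [probs[b] for b in BASES])
        rates[i] = rate_from_counts(dict(zip(BASES, counts.tolist())), profile)
    return rates


def run_sweep(spec: SimulationSpec, profile: Profile = Profile.PAPER) -> pd.DataFrame:
    """Mean/SD compression rate for every (length, dominant_fraction) cell.

    Deterministic given ``spec.seed``. Returns a DataFrame with columns
    length, dominant_fraction, n, mean_rate, sd_rate.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for frac in spec.dominant_fractions:
        for length in spec.lengths:
            rates = simulate_rates(
                length, frac, spec.dominant_base, spec.replicates, rng, profile
            )
            rows.append(
                {
                    "length": length,
                    "dominant_fraction": frac,
                    "n": spec.replicates,
                    "mean_rate": rates.mean(),
                    "sd_rate": rates.std(ddof=1) if len(rates) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


class ComparatorCompressor(Protocol):
    """Anything reporting a compressed size in output characters."""

    def compress_size(self, seq: str) -> float: ...


class IdentityComparator:
    """Output size equals input size (rate 1); a null baseline."""

    def compress_size(self, seq: str) -> float:
        return float(len(seq))


class TwoBitPackerComparator:
    """Fixed 2-bit packing reported in Base64-equivalent characters."""

    def compress_size(self, seq: str) -> float:
        return -(-2 * len(seq) // 6)


class DdqrComparator:
    """DDQR itself; the self-ratio is 1 everywhere."""

    def __init__(self, profile: Profile = Profile.PAPER):
        self.profile = profile

    def compress_size(self, seq: str) -> float:
        return float(len(ddqr_encode(seq, self.profile)))


class SubprocessComparator:
    """Adapter for an external compressor binary (e.g. GeCo3).

    ``command`` is a template whose ``{input}`` placeholder receives a path
    to a one-record FASTA file; the compressed size in bytes is read from
    the tool's standard output (last whitespace-separated number). Never
    required by the test suite.
    """

    def __init__(self, command: str):
        self.command = command

    def compress_size(self, seq: str) -> float:
        import re
        import subprocess
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
            fh.write(">seq\n")
            fh.write(seq + "\n")
            path = fh.name
        out = subprocess.run(
            self.command.format(input=path),
            shell=True,
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        numbers = re.findall(r"[-+]?\d*\.?\d+", out)
        if not numbers:
            raise RuntimeError(f"no size in comparator output: {out!r}")
        return float(numbers[-1])


def ratio_series(
    spec: SimulationSpec,
    comparator: ComparatorCompressor,
    profile: Profile = Profile.PAPER,
) -> pd.DataFrame:
    """Per-length ratio of mean DDQR rate to mean comparator rate.

    Uses the first entry of ``spec.dominant_fractions``. Lengths where the
    comparator fails on every replicate are skipped with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    rng = np.random.default_rng(spec.seed)
    frac = spec.dominant_fractions[0]
    rows = []
    for length in spec.lengths:
        ddqr_rates = []
        comp_rates = []
        for _ in range(spec.replicates):
            seq = generate_sequence(length, frac, spec.dominant_base, rng)
            try:
                comp = comparator.compress_size(seq) / length
            except Exception as exc:  # comparator failure: skip the replicate
                log.warning("comparator failed at length %d: %s", length, exc)
                continue
            ddqr_rates.append(len(ddqr_encode(seq, profile)) / length)
            comp_rates.append(comp)
        if not comp_rates:
            log.warning("no comparator results at length %d; cell skipped", length)
            continue
        rows.append(
            {
                "length": length,
                "ratio": float(np.mean(ddqr_rates) / np.mean(comp_rates)),
            }
        )
    return pd.DataFrame(rows)


def detect_cutoff(
    series: pd.DataFrame, window: int = 10, vote_threshold: int = 6
) -> CutoffResult:
    """Sliding-window crossover detection on a consecutive-length ratio series.

    The window at length i covers the ``window + 1`` ratios for lengths
    (i - window)..i; at the first i where at least ``vote_threshold`` of
    them exceed 1 the cutoff is declared at i - window//2. Returns
    cutoff_length None when never triggered.
    """
    lengths = series["length"].to_numpy()
    ratios = series["ratio"].to_numpy()
    if len(lengths) < window + 1:
        raise InsufficientDataError(
            f"need at least {window + 1} consecutive lengths, got {len(lengths)}"
        )
    if not np.all(np.diff(lengths) == 1):
        raise InsufficientDataError("lengths must be consecutive with step 1")
    above = ratios > 1
    for k in range(window, len(lengths)):
        if int(above[k - window : k + 1].sum()) >= vote_threshold:
            return CutoffResult(
                float(lengths[k] - window // 2), window, vote_threshold
            )
    return CutoffResult(None, window, vote_threshold)


def mean_cutoff(cutoffs: list[CutoffResult]) -> float | None:
    """Average the defined cutoffs of replicate series (fractional result)."""
    vals = [c.cutoff_length for c in cutoffs if c.cutoff_length is not None]
    return float(np.mean(vals)) if vals else None
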