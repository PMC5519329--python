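"""Synthetic data generators for every input class of the pipeline.

Two families of generators:

* ``gen_zf_family`` emits protein sequences built as tandem repeats of a
  mutated ancestral 28-aa C2H2 finger.  Substitutions fall independently
  per finger and position at a configurable rate; positions 11, 12, 15
  and 18 (the DNA-binding residues) receive the rate times a multiplier,
  so a multiplier of 1 gives a neutral background gene family while a
  large multiplier produces a PRDM9-like gene whose diversity concentrates
  at binding sites.  The four C/H anchors never mutate.  An optional
  finger-conversion step emulates concerted evolution (paralogous gene
  conversion homogenising the array).

* ``gen_landscape`` emits a miniature genome: contig sizes, uniformly
  placed TSS/CGI features, H3K4me3-like peak sets, and crossover
  intervals whose midpoints are drawn either uniformly or with intensity
  1 + A*exp(-d/lambda) around a chosen feature class.  Event lengths are
  log-normal with a median of 13 kb and 75th percentile of 35 kb by
  default, matching the resolution profile of ancestry-switch intervals
  in low-coverage hybrid data.

All generators are pure functions of (config, seed): rerunning with the
same configuration reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .motif import PWM

#: 0-based anchor positions within the 28-aa finger.
_ANCHOR0 = {2: "C", 5: "C", 18: "H", 22: "H"}
_MUTABLE = [i for i in range(28) if i not in _ANCHOR0]
_BINDING0 = [10, 11, 14, 17]  # 1-based 11, 12, 15, 18
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# log-normal event lengths: median 13 kb fixes mu; the 75th percentile of
# 35 kb fixes sigma via the 0.6745 upper-quartile z-score.
DEFAULT_LENGTH_MEDIAN = 13_000.0
DEFAULT_LENGTH_Q75 = 35_000.0
_Z75 = 0.6744897501960817


def lognormal_params(median: float, q75: float) -> tuple[float, float]:
    """Solve (mu, sigma) of a log-normal from its median and 75th percentile."""
    if not 0 < median < q75:
        raise ValueError("need 0 < median < q75")
    mu = math.log(median)
    sigma = (math.log(q75) - mu) / _Z75
    return mu, sigma


@dataclasses.dataclass
class ZFFamilyConfig:
    """Configuration of one synthetic C2H2 ZF gene family."""

    n_genes: int = 200
    n_fingers: int = 10
    sub_rate: float = 0.08          # per-position, per-finger substitution prob
    binding_multiplier: float = 1.0  # rate multiplier at positions 11/12/15/18
    conversion_rate: float = 0.0    # per-finger prob of being overwritten by a paralog
    gene_prefix: str = "gene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sub_rate < 0 or self.binding_multiplier < 1:
            raise ValueError("sub_rate >= 0 and binding_multiplier >= 1 required")
        if self.conversion_rate < 0:
            raise ValueError("conversion_rate >= 0 required")


def _random_ancestral_finger(rng: np.random.Generator) -> list[str]:
    finger = [""] * 28
    for i in range(28):
        finger[i] = _ANCHOR0.get(i) or _AA20[rng.integers(len(_AA20))]
    return finger


def gen_zf_family(config: ZFFamilyConfig) -> list[tuple[str, str]]:
    """Generate (id, protein sequence) records for one ZF gene family.

    Each gene is an independently drawn ancestral finger repeated
    ``n_fingers`` times, then mutated per position and finger.  Mutations
    replace the residue with a uniformly drawn *different* standard amino
    acid.  With conversion, each finger may then be overwritten by a copy
    of another (randomly chosen) finger of the same gene, homogenising
    the array the way paralogous gene conversion does.
    """
    rng = np.random.default_rng(config.seed)
    rates = np.zeros(28)
    rates[_MUTABLE] = config.sub_rate
    for b in _BINDING0:
        rates[b] = min(1.0, config.sub_rate * config.binding_multiplier)

    records = []
    for g in range(config.n_genes):
        ancestor = _random_ancestral_finger(rng)
        fingers = [list(ancestor) for _ in range(config.n_fingers)]
        mutate = rng.random((config.n_fingers, 28)) < rates[None, :]
        for fi, pos in zip(*np.nonzero(mutate)):
            current = fingers[fi][pos]
            choices = [a for a in _AA20 if a != current]
            fingers[fi][pos] = choices[rng.integers(len(choices))]
        if config.conversion_rate > 0 and config.n_fingers > 1:
            convert = rng.random(config.n_fingers) < config.conversion_rate
            snapshot = [list(f) for f in fingers]
            for fi in np.nonzero(convert)[0]:
                donor = rng.integers(config.n_fingers - 1)
                if donor >= fi:
                    donor += 1
                fingers[fi] = list(snapshot[donor])
        seq = "M" + "".join("".join(f) for f in fingers)
        records.append((f"{config.gene_prefix}{g:04d}", seq))
    return records


@dataclasses.dataclass
class LandscapeConfig:
    """Configuration of a synthetic genome + crossover landscape."""

    contig_lengths: tuple[int, ...] = (2_000_000,) * 5
    n_tss: int = 100
    n_cgi: int = 100
    n_peaks: int = 100
    peak_width: int = 230            # H3K4me3-like peak width
    feature_width: int = 200
    peak_model: str = "uniform"      # uniform | at_features
    crossover_model: str = "uniform"  # uniform | feature | peak | motif
    intensity_amplitude: float = 5.0  # A in 1 + A*exp(-d/lambda)
    decay_bp: float = 20_000.0        # lambda
    n_events: int = 2_000
    length_median: float = DEFAULT_LENGTH_MEDIAN
    length_q75: float = DEFAULT_LENGTH_Q75
    make_genome: bool = False         # random ACGT sequence (needed for scans)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events >= 1 required")
        if self.intensity_amplitude < 0 or self.decay_bp <= 0:
            raise ValueError("intensity parameters must be positive")
        if not self.contig_lengths or min(self.contig_lengths) <= 0:
            raise ValueError("contig lengths must be positive")


@dataclasses.dataclass
class Landscape:
    contig_sizes: dict[str, int]
    tss: pd.DataFrame
    cgi: pd.DataFrame
    peaks: pd.DataFrame
    events: pd.DataFrame
    genome: dict[str, str] | None = None


def _uniform_positions(
    rng: np.random.Generator, contig_sizes: Mapping[str, int], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """n positions uniform over the concatenated genome -> (chrom idx, pos)."""
    names = list(contig_sizes)
    lengths = np.array([contig_sizes[c] for c in names], dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("empty genome")
    flat = rng.random(n) * total
    bounds = np.concatenate([[0.0], np.cumsum(lengths)])
    ci = np.searchsorted(bounds, flat, side="right") - 1
    pos = flat - bounds[ci]
    return ci, pos


def _interval_frame(
    names: list[str], ci: np.ndarray, centers: np.ndarray, width: int,
    sizes: np.ndarray,
) -> pd.DataFrame:
    start = np.maximum(0, (centers - width / 2).astype(int))
    end = np.minimum(sizes[ci].astype(int), start + width)
    start = np.maximum(0, end - width)
    df = pd.DataFrame(
        {"chrom": [names[i] for i in ci], "start": start, "end": end}
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _distance_to_features(
    names: list[str], ci: np.ndarray, pos: np.ndarray, features: pd.DataFrame
) -> np.ndarray:
    from .recomb import _nearest_distance

    d = np.full(len(pos), np.inf)
    for idx, chrom in enumerate(names):
        mask = ci == idx
        if not mask.any():
            continue
        grp = features[features["chrom"] == chrom].sort_values("start")
        if len(grp) == 0:
            continue
        d[mask] = _nearest_distance(
            pos[mask],
            grp["start"].to_numpy(dtype=float),
            grp["end"].to_numpy(dtype=float),
        )
    return d


def gen_landscape(
    config: LandscapeConfig,
    target_features: pd.DataFrame | None = None,
) -> Landscape:
    """Generate a coordinate-consistent synthetic recombination landscape.

    Crossover midpoints are sampled by rejection: a uniform proposal at
    distance d from the nearest target feature is accepted with
    probability (1 + A*exp(-d/lambda)) / (1 + A), which realises the
    intensity profile 1 + A*exp(-d/lambda) exactly.  Event intervals are
    centred on midpoints with log-normal lengths, clipped to the contig.

    ``crossover_model="motif"`` directs events at externally supplied
    intervals (``target_features``), e.g. planted motif sites from
    :func:`plant_motifs`.
    """
    rng = np.random.default_rng(config.seed)
    names = [f"contig{i}" for i in range(len(config.contig_lengths))]
    contig_sizes = dict(zip(names, (int(x) for x in config.contig_lengths)))
    sizes = np.array([contig_sizes[c] for c in names], dtype=float)

    ci, pos = _uniform_positions(rng, contig_sizes, config.n_tss)
    tss = _interval_frame(names, ci, pos, config.feature_width, sizes)
    ci, pos = _uniform_positions(rng, contig_sizes, config.n_cgi)
    cgi = _interval_frame(names, ci, pos, config.feature_width, sizes)

    genome = None
    if config.make_genome:
        genome = {
            c: "".join(
                np.array(list("ACGT"))[rng.integers(4, size=contig_sizes[c])]
            )
            for c in names
        }

    if config.peak_model == "uniform":
        ci, pos = _uniform_positions(rng, contig_sizes, config.n_peaks)
        peaks = _interval_frame(names, ci, pos, config.peak_width, sizes)
    elif config.peak_model == "at_features":
        take = rng.integers(0, len(tss), config.n_peaks)
        centers = ((tss["start"] + tss["end"]) / 2).to_numpy()[take]
        chrom_idx = np.array([names.index(c) for c in tss["chrom"].iloc[take]])
        jitter = rng.normal(0, config.peak_width, config.n_peaks)
        centers = np.clip(centers + jitter, 0, sizes[chrom_idx] - 1)
        peaks = _interval_frame(names, chrom_idx, centers, config.peak_width, sizes)
    else:
        raise ValueError(f"unknown peak model {config.peak_model!r}")

    if config.crossover_model == "motif" and target_features is None:
        raise ValueError("crossover_model='motif' requires target_features")
    target = {
        "uniform": None,
        "feature": tss,
        "peak": peaks,
        "motif": target_features,
    }.get(config.crossover_model, "missing")
    if isinstance(target, str):
        raise ValueError(f"unknown crossover model {config.crossover_model!r}")

    mids_ci = np.empty(0, dtype=int)
    mids = np.empty(0)
    while len(mids) < config.n_events:
        batch = max(4 * (config.n_events - len(mids)), 1000)
        ci, pos = _uniform_positions(rng, contig_sizes, batch)
        if target is None:
            accept = np.ones(batch, dtype=bool)
        else:
            d = _distance_to_features(names, ci, pos, target)
            a, lam = config.intensity_amplitude, config.decay_bp
            intensity = 1.0 + a * np.exp(-np.where(np.isfinite(d), d, np.inf) / lam)
            accept = rng.random(batch) < intensity / (1.0 + a)
        mids_ci = np.concatenate([mids_ci, ci[accept]])
        mids = np.concatenate([mids, pos[accept]])
    mids_ci = mids_ci[: config.n_events]
    mids = mids[: config.n_events]

    mu, sigma = lognormal_params(config.length_median, config.length_q75)
    lengths = np.exp(rng.normal(mu, sigma, config.n_events))
    start = np.maximum(0, (mids - lengths / 2).astype(int))
    end = np.minimum(sizes[mids_ci].astype(int), (mids + lengths / 2).astype(int))
    end = np.maximum(end, start + 1)
    end = np.minimum(end, sizes[mids_ci].astype(int))
    start = np.minimum(start, end - 1)
    events = pd.DataFrame(
        {"chrom": [names[i] for i in mids_ci], "start": start, "end": end}
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    return Landscape(
        contig_sizes=contig_sizes,
        tss=tss,
        cgi=cgi,
        peaks=peaks,
        events=events,
        genome=genome,
    )


def plant_motifs(
    genome: Mapping[str, str],
    pwm: PWM,
    n_sites: int,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write the PWM consensus at non-overlapping random genome positions.

    Returns the modified genome and an exact BED-like table of the planted
    sites.  Raises if non-overlapping placement fails within the retry
    budget (the genome must be comfortably larger than n_sites * L).
    """
    rng = np.random.default_rng(rng)
    L = len(pwm)
    total = sum(len(s) for s in genome.values())
    if n_sites * L >= total / 10:
        raise ValueError("too many sites for genome size")
    consensus = pwm.consensus
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    names = list(genome)
    lengths = np.array([len(genome[c]) for c in names], dtype=float)
    rows = []
    for _ in range(n_sites):
        for _try in range(max_tries):
            ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
            chrom = names[ci]
            if len(genome[chrom]) < L:
                continue
            start = int(rng.integers(0, len(genome[chrom]) - L + 1))
            if all(
                start + L <= s or start >= e for s, e in placed[chrom]
            ):
                placed[chrom].append((start, start + L))
                rows.append((chrom, start, start + L))
                break
        else:
            raise RuntimeError(
                f"could not place motif site without overlap after {max_tries} tries"
            )
    new_genome = {}
    for chrom, seq in genome.items():
        s = list(seq)
        for start, end in placed[chrom]:
            s[start:end] = consensus
        new_genome[chrom] = "".join(s)
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return new_genome, sites.sort_values(["chrom", "start"]).reset_index(drop=True)
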