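"""Per-site heterozygosity across a tandem ZF array and the empirical ranking
that flags rapid evolution of DNA-binding residues.

For position ``k`` of the 28-aa finger alignment implied by a tandem array,
the heterozygosity is

    x_k = 1 - sum_i f_i**2

where ``f_i`` is the frequency of the i-th distinct residue at position k
across the fingers of the array.  The statistic P is the share of total
diversity carried by the canonical DNA-binding residues (array positions
11, 12, 15 and 18, 1-based):

    P = sum_{k in binding} x_k / sum_k x_k

High P is the signature of positive selection on binding affinity combined
with concerted evolution of the array: diversity concentrates at the
base-contacting side chains while the structural scaffold homogenises.
Significance is assessed empirically, by ranking PRDM9's P against every
other C2H2 ZF gene of the same species, rather than by dN/dS (paralogous
gene conversion leaves no single tree relating the fingers).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .zf_domains import FINGER_LEN, ZFArray

#: Canonical DNA-binding positions of the 28-aa finger, 1-based.
BINDING_POSITIONS = frozenset({11, 12, 15, 18})
#: Zinc-coordinating anchors, 1-based; monomorphic whenever the motif holds.
ANCHOR_POSITIONS = frozenset({3, 6, 19, 23})


@dataclasses.dataclass
class DiversityProfile:
    """Per-position heterozygosity for one gene's selected array."""

    gene_id: str
    x: np.ndarray  # length-28 vector of x_k
    n_fingers: int
    P: float | None  # None == NA (monomorphic array)
    binding_positions: frozenset[int] = BINDING_POSITIONS
    has_ambiguous: bool = False


@dataclasses.dataclass
class SpeciesRanking:
    """Competition ranking of genes by descending P within one species."""

    species: str
    table: pd.DataFrame  # columns: gene_id, P, rank
    prdm9_ids: list[str]
    n_genes: int
    prdm9_percentile: dict[str, float]  # rank / n_genes, per PRDM9 id


def site_heterozygosity(array: ZFArray | Sequence[str]) -> np.ndarray:
    """Compute x_k = 1 - sum f_i^2 at each position across the fingers.

    With a single finger every column is monomorphic and the vector is all
    zeros.  Fingers of unequal length are rejected.
    """
    seqs = array.sequences if isinstance(array, ZFArray) else list(array)
    if not seqs:
        raise ValueError("array has no fingers")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("fingers have unequal lengths")
    n = len(seqs)
    x = np.zeros(length)
    for k in range(length):
        counts = Counter(s[k] for s in seqs)
        freqs = np.array(list(counts.values()), dtype=float) / n
        x[k] = 1.0 - np.sum(freqs**2)
    return x


def binding_site_proportion(
    x: np.ndarray,
    binding_positions: Iterable[int] = BINDING_POSITIONS,
) -> float | None:
    """P = diversity at binding sites / total diversity; None when total is 0."""
    x = np.asarray(x, dtype=float)
    positions = sorted(set(binding_positions))
    for pos in positions:
        if not 1 <= pos <= len(x):
            raise ValueError(f"binding position {pos} outside 1..{len(x)}")
    total = float(x.sum())
    if total == 0.0:
        return None
    idx = np.array(positions) - 1
    return float(x[idx].sum() / total)


def profile_from_array(
    array: ZFArray,
    binding_positions: Iterable[int] = BINDING_POSITIONS,
) -> DiversityProfile:
    """Convenience: heterozygosity vector and P for one array."""
    x = site_heterozygosity(array)
    return DiversityProfile(
        gene_id=array.gene_id,
        x=x,
        n_fingers=len(array),
        P=binding_site_proportion(x, binding_positions),
        binding_positions=frozenset(binding_positions),
        has_ambiguous=array.has_ambiguous,
    )


def rank_in_species(
    profiles: Sequence[DiversityProfile],
    prdm9_ids: Iterable[str],
    species: str = "",
) -> SpeciesRanking:
    """Rank genes by descending P with competition (minimum) ranks.

    Genes whose P is NA (monomorphic arrays) are excluded both from the
    ranking and from the denominator ``n_genes`` — they receive no rank at
    all, mirroring how a gene with no amino-acid diversity between its
    fingers is reported.  Ties share the smallest rank of the tied block,
    which is conservative for the top-fraction call.
    """
    if not profiles:
        raise ValueError("no profiles to rank")
    prdm9_ids = list(prdm9_ids)
    known = {p.gene_id for p in profiles}
    missing = [g for g in prdm9_ids if g not in known]
    if missing:
        raise ValueError(f"PRDM9 id(s) not among profiles: {missing}")

    defined = [(p.gene_id, p.P) for p in profiles if p.P is not None]
    table = pd.DataFrame(defined, columns=["gene_id", "P"])
    if len(table):
        table["rank"] = (
            table["P"].rank(method="min", ascending=False).astype(int)
        )
    else:
        table["rank"] = pd.Series(dtype=int)
    n_genes = len(table)
    ranks = dict(zip(table["gene_id"], table["rank"]))
    percentile = {
        g: ranks[g] / n_genes for g in prdm9_ids if g in ranks
    }
    return SpeciesRanking(
        species=species,
        table=table.sort_values("rank", kind="stable").reset_index(drop=True),
        prdm9_ids=prdm9_ids,
        n_genes=n_genes,
        prdm9_percentile=percentile,
    )


def classify_rapid(
    ranking: SpeciesRanking, alpha: float = 0.05
) -> dict[str, dict[str, bool]]:
    """Flag each PRDM9 id: rapid (percentile <= alpha) and ranked-first.

    A PRDM9 whose own P is NA gets both flags False (it cannot demonstrate
    rapid evolution without diversity).  Note that small gene panels cannot
    clear the threshold even at rank 1: rank 1 of 10 is percentile 0.1.
    """
    ranks = dict(zip(ranking.table["gene_id"], ranking.table["rank"]))
    flags = {}
    for gene in ranking.prdm9_ids:
        pct = ranking.prdm9_percentile.get(gene)
        flags[gene] = {
            "rapid": pct is not None and pct <= alpha,
            "first": ranks.get(gene) == 1,
        }
    return flags


def diversity_profile_bands(
    profiles: Sequence[DiversityProfile],
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Per-position quantile envelope of x_k across a set of background genes.

    Returns a DataFrame indexed by 1-based position with columns ``lo`` and
    ``hi`` — the background band against which a focal (PRDM9) profile is
    plotted to show where its diversity escapes the genome-wide range.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for an envelope")
    lo_q, hi_q = quantiles
    mat = np.vstack([p.x for p in profiles])
    lo = np.quantile(mat, lo_q, axis=0)
    hi = np.quantile(mat, hi_q, axis=0)
    return pd.DataFrame(
        {"position": np.arange(1, mat.shape[1] + 1), "lo": lo, "hi": hi}
    ).set_index("position")


def profiles_from_proteins(
    records: Mapping[str, str] | Sequence[tuple[str, str]],
    use_all_fingers: bool = False,
    gap_tolerance: int = 0,
    min_fingers: int = 4,
    binding_positions: Iterable[int] = BINDING_POSITIONS,
) -> tuple[list[DiversityProfile], dict[str, int]]:
    """Parse proteins and compute one profile per gene with a qualifying array.

    By default only the first array of >= ``min_fingers`` adjacent fingers
    is used; ``use_all_fingers=True`` pools every parsed finger of the gene
    instead (the sensitivity analysis for genes with several short arrays).
    Both modes agree exactly for single-array proteins.

    Returns the profiles and a log of counts: parsed genes, genes dropped
    for lacking a qualifying array, genes with NA (monomorphic) P.
    """
    from .zf_domains import ZFArray, extract_arrays, parse_zf_fingers

    items = records.items() if isinstance(records, Mapping) else records
    profiles: list[DiversityProfile] = []
    log = {"n_input": 0, "n_no_array": 0, "n_na": 0}
    for gene_id, seq in items:
        log["n_input"] += 1
        fingers = parse_zf_fingers(seq)
        if use_all_fingers:
            if len(fingers) < min_fingers:
                log["n_no_array"] += 1
                continue
            array = ZFArray(gene_id=gene_id, fingers=list(fingers))
        else:
            arrays = extract_arrays(
                fingers, gap_tolerance=gap_tolerance,
                min_fingers=min_fingers, gene_id=gene_id,
            )
            if not arrays:
                log["n_no_array"] += 1
                continue
            array = arrays[0]
        prof = profile_from_array(array, binding_positions)
        if prof.P is None:
            log["n_na"] += 1
        profiles.append(prof)
    return profiles, log
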