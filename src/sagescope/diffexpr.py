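"""Fold-change differential expression between two SAGE libraries.

With one pooled library per condition there are no replicates, so genes
are called differentially expressed by effect size alone: a gene passes
if it is reasonably abundant (TPM above a threshold, default 10, in at
least one condition) and changes at least ``fc_min``-fold (default 2) in
either direction.

Zero handling: a gene observed in only one library has no defined ratio,
so the zero side is replaced by the TPM equivalent of a single tag in
that library (one tag in ~5 million mapped tags is 0.2 TPM).  The
pseudo-count therefore depends on each library's own total.  A gene with
zero in both libraries is skipped.

This module also computes the abundance-distribution profile (how few
high-TPM genes carry most of the library) and the log2 FC-vs-TPM scatter
points used to visualise the selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .quantify import ExpressionProfile, tpm

DEFAULT_TPM_MIN = 10.0
DEFAULT_FC_MIN = 2.0
# powers of ten over the observable TPM range; 0.2 TPM = one tag in 5M
DEFAULT_BIN_EDGES = (0.2, 1.0, 10.0, 100.0, 1_000.0, 10_000.0, math.inf)


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    tpm_control: float
    tpm_treated: float
    fold_change: float  # treated / control after zero handling, > 0
    passes_tpm_filter: bool
    passes_fc_filter: bool

    @property
    def direction(self) -> str:
        return "up" if self.fold_change >= 1 else "down"

    @property
    def magnitude(self) -> float:
        """max(FC, 1/FC) — the two-sided fold change the filter tests."""
        return max(self.fold_change, 1.0 / self.fold_change)


def fold_change(
    tpm_treated: float,
    tpm_control: float,
    total_treated: int,
    total_control: int,
) -> float | None:
    """Treated/control TPM ratio with single-tag pseudo-count on zeros.

    Returns None (skip) when both TPMs are zero; no replacement happens
    when both are positive.
    """
    if tpm_treated < 0 or tpm_control < 0:
        raise ValueError("TPM must be non-negative")
    if tpm_treated == 0 and tpm_control == 0:
        return None
    t = tpm_treated if tpm_treated > 0 else tpm(1, total_treated)
    c = tpm_control if tpm_control > 0 else tpm(1, total_control)
    return t / c


def evaluate_de(
    tpm_control: Mapping[str, float],
    tpm_treated: Mapping[str, float],
    total_control: int,
    total_treated: int,
    tpm_min: float = DEFAULT_TPM_MIN,
    fc_min: float = DEFAULT_FC_MIN,
    strict_fc: bool = False,
    inclusive_tpm: bool = False,
) -> list[DEGene]:
    """Evaluate every gene present in either library.

    ``strict_fc`` switches the fold-change filter from >= to >;
    ``inclusive_tpm`` switches the abundance filter from > to >=.
    Genes with zero TPM in both libraries are skipped.
    """
    genes = sorted(set(tpm_control) | set(tpm_treated))
    out = []
    for gene in genes:
        c = tpm_control.get(gene, 0.0)
        t = tpm_treated.get(gene, 0.0)
        fc = fold_change(t, c, total_treated, total_control)
        if fc is None:
            continue
        if inclusive_tpm:
            passes_tpm = c >= tpm_min or t >= tpm_min
        else:
            passes_tpm = c > tpm_min or t > tpm_min
        magnitude = max(fc, 1.0 / fc)
        passes_fc = magnitude > fc_min if strict_fc else magnitude >= fc_min
        out.append(DEGene(gene, c, t, fc, passes_tpm, passes_fc))
    return out


def select_de(
    profile_control: ExpressionProfile,
    profile_treated: ExpressionProfile,
    tpm_min: float = DEFAULT_TPM_MIN,
    fc_min: float = DEFAULT_FC_MIN,
    strict_fc: bool = False,
    inclusive_tpm: bool = False,
) -> tuple[list[DEGene], dict[str, int]]:
    """Differentially expressed genes between two profiles.

    Returns the genes passing both filters and a summary with up/down
    counts.
    """
    if not profile_control.counts or not profile_treated.counts:
        raise ValueError("both profiles must be non-empty")
    evaluated = evaluate_de(
        profile_control.tpm,
        profile_treated.tpm,
        profile_control.total_mapped,
        profile_treated.total_mapped,
        tpm_min=tpm_min,
        fc_min=fc_min,
        strict_fc=strict_fc,
        inclusive_tpm=inclusive_tpm,
    )
    selected = [g for g in evaluated if g.passes_tpm_filter and g.passes_fc_filter]
    summary = {
        "n_evaluated": len(evaluated),
        "n_de": len(selected),
        "n_up": sum(1 for g in selected if g.direction == "up"),
        "n_down": sum(1 for g in selected if g.direction == "down"),
    }
    return selected, summary


# ---------------------------------------------------------------------------
# Abundance profiling


@dataclass
class AbundanceProfile:
    """Distribution of gene entries and tag mass over TPM bins."""

    bin_edges: tuple[float, ...]  # upper edges; bin i is (prev, edge_i]
    entries_per_bin: list[int]
    tag_fraction_per_bin: list[float]

    @property
    def cumulative_entries(self) -> list[int]:
        return list(np.cumsum(self.entries_per_bin))

    @property
    def cumulative_tag_fraction(self) -> list[float]:
        return list(np.cumsum(self.tag_fraction_per_bin))

    @property
    def n_entries(self) -> int:
        return sum(self.entries_per_bin)


def abundance_profile(
    profile: ExpressionProfile,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> AbundanceProfile:
    """Bin expressed genes by TPM; report entry counts and tag fractions.

    ``bin_edges`` are strictly increasing upper edges; the first bin is
    (0, edges[0]] and the last edge should be inf to cover all genes.
    """
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if edges[-1] != math.inf:
        edges = edges + (math.inf,)

    tpms = np.array([profile.tpm[g] for g in sorted(profile.tpm)])
    counts = np.array([profile.counts[g] for g in sorted(profile.counts)])
    entries = []
    fractions = []
    lo = 0.0
    total = counts.sum()
    for hi in edges:
        in_bin = (tpms > lo) & (tpms <= hi)
        entries.append(int(in_bin.sum()))
        fractions.append(float(counts[in_bin].sum() / total) if total else 0.0)
        lo = hi
    return AbundanceProfile(edges, entries, fractions)


def entries_above(profile: ExpressionProfile, threshold: float) -> tuple[int, float]:
    """(number of genes with TPM > threshold, fraction of tags they carry)."""
    n = 0
    mass = 0
    for gene, value in profile.tpm.items():
        if value > threshold:
            n += 1
            mass += profile.counts[gene]
    frac = mass / profile.total_mapped if profile.total_mapped else 0.0
    return n, frac


def fc_vs_tpm_points(de_genes: Sequence[DEGene]) -> list[tuple[float, float]]:
    """(log2 treated TPM, log2 fold change) per gene with a defined FC.

    The x coordinate uses the treated library's TPM after zero handling
    (a zero is the single-tag pseudo-count divided out of the stored FC).
    """
    points = []
    for g in de_genes:
        # FC = t_eff / c_eff, so a zero treated TPM back-computes from the
        # stored fold change and the (necessarily positive) control TPM
        t = g.tpm_treated if g.tpm_treated > 0 else g.fold_change * g.tpm_control
        points.append((math.log2(t), math.log2(g.fold_change)))
    return points
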