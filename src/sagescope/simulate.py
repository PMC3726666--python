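"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design end to end: a toy reference
transcriptome in which every gene yields a usable virtual tag; a pair of
SAGE libraries (control and treated) drawn multinomially from a heavily
skewed abundance distribution, with planted fold-change effects and
independent per-base substitution errors; gene-set collections with
planted over-representation of a designated DE list; and per-individual
qPCR Ct tables with known log2 fold changes.

Abundances are log-normal on the TPM scale, renormalised to 1e6.  The
default dispersion (sigma of the natural-log scale = 3.5 at 2,000 genes)
reproduces the shape of real SAGE libraries where roughly a tenth of
gene entries sit above 100 TPM yet carry the large majority of all tags.
Every generator is deterministic given the manifest and its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binom

from .enrich import GeneSet
from .quantify import TagObservation
from .tagdb import ANCHOR, TranscriptRecord, extract_virtual_tags

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STREAMS = {"transcriptome": 11, "abundance": 13, "library": 17, "sets": 19, "ct": 23}


@dataclass
class SimulationManifest:
    """Parameters that fully determine every generated byte.

    ``n_tags_per_library`` defaults to 2e6 — large enough for stable TPM
    at desk scale; the study's full 13.6M-tag depth is reached by simply
    raising it.  ``per_base_error_rate`` is per sequenced base;
    ``ct_noise_sd`` is the technical Ct noise in cycles.
    """

    seed: int = 0
    n_genes: int = 2000
    transcript_length_range: tuple[int, int] = (300, 1500)
    tag_length: int = 27
    abundance_sigma: float = 3.5  # lognormal sigma, natural-log scale
    tpm_cap: float = 150_000.0  # no single transcript above ~15% of the library
    n_de_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"4.0": 100, "0.25": 100, "2.0": 50, "0.5": 50}
    )
    de_effects: dict[str, float] | None = None  # explicit gene -> effect overrides
    n_tags_per_library: int = 2_000_000
    per_base_error_rate: float = 0.005
    ct_noise_sd: float = 0.25
    ct_replicates: int = 3
    ct_baseline_range: tuple[float, float] = (18.0, 26.0)

    def rng(self, stream: str, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream], salt])

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["n_de_per_class"] = dict(self.n_de_per_class)
        data["transcript_length_range"] = list(self.transcript_length_range)
        data["ct_baseline_range"] = list(self.ct_baseline_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationManifest":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("transcript_length_range", "ct_baseline_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Transcriptome


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_transcriptome(manifest: SimulationManifest) -> list[TranscriptRecord]:
    """Random transcripts, one per gene, each with a guaranteed tag.

    The 3' end of each transcript is constructed as CATG plus a random
    tag body that is rescreened so no accidental downstream CATG
    displaces the intended anchor; the rest of the sequence is random.
    """
    rng = manifest.rng("transcriptome")
    lo, hi = manifest.transcript_length_range
    tail = manifest.tag_length - len(ANCHOR)
    records = []
    for i, gene in enumerate(manifest.gene_ids(), start=1):
        body_len = int(rng.integers(lo, hi + 1)) - manifest.tag_length
        body = _random_seq(rng, max(body_len, 0)).tobytes().decode()
        while True:
            tag_body = _random_seq(rng, tail).tobytes().decode()
            window = ANCHOR + tag_body
            if window.rfind(ANCHOR) == 0:
                break
        records.append(
            TranscriptRecord(
                transcript_id=f"tx{i:05d}",
                gene_id=gene,
                sequence=body + window,
            )
        )
    return records


def write_transcriptome_fasta(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id} gene={rec.gene_id}\n")
            for start in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[start : start + 70] + "\n")


# ---------------------------------------------------------------------------
# Abundances and planted effects


def default_de_effects(manifest: SimulationManifest) -> dict[str, float]:
    """Planted fold-change effects: which genes change and by how much.

    Genes are drawn without replacement from the whole roster; everything
    not listed has effect 1 (null).
    """
    if manifest.de_effects is not None:
        return dict(manifest.de_effects)
    rng = manifest.rng("abundance", salt=1)
    genes = manifest.gene_ids()
    n_needed = sum(manifest.n_de_per_class.values())
    chosen = rng.choice(len(genes), size=n_needed, replace=False)
    effects: dict[str, float] = {}
    pos = 0
    for effect_str, count in sorted(manifest.n_de_per_class.items()):
        for j in chosen[pos : pos + count]:
            effects[genes[j]] = float(effect_str)
        pos += count
    return effects


def simulate_abundances(manifest: SimulationManifest) -> pd.DataFrame:
    """True TPM per gene in each condition, plus planted effect and FC.

    Control TPMs are capped log-normal draws renormalised to 1e6; the
    treated condition multiplies by each gene's planted effect and
    renormalises again, so the realised treated/control TPM ratio
    (``true_fc``) differs from the planted effect by the common
    renormalisation factor.
    """
    rng = manifest.rng("abundance")
    genes = manifest.gene_ids()
    raw = rng.lognormal(mean=0.0, sigma=manifest.abundance_sigma, size=len(genes))
    raw = np.minimum(raw, manifest.tpm_cap * raw.sum() / 1e6)  # cap relative mass
    control = raw * 1e6 / raw.sum()
    effects = default_de_effects(manifest)
    effect_vec = np.array([effects.get(g, 1.0) for g in genes])
    treated = control * effect_vec
    treated *= 1e6 / treated.sum()
    return pd.DataFrame(
        {
            "gene_id": genes,
            "tpm_control": control,
            "tpm_treated": treated,
            "de_effect": effect_vec,
            "true_fc": treated / control,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Library simulation


def _mutate_tags(
    rng: np.random.Generator,
    base_codes: np.ndarray,  # (n_reads, L) uint8 base codes of the true tags
    error_rate: float,
) -> np.ndarray:
    """Apply >= 1 substitution per read, Binomial(L, e)-conditioned."""
    n, L = base_codes.shape
    # conditional distribution of the error count given >= 1 error
    ks = np.arange(1, min(L, 6) + 1)
    pmf = binom.pmf(ks, L, error_rate)
    pmf = pmf / pmf.sum()
    n_err = rng.choice(ks, size=n, p=pmf)
    out = base_codes.copy()
    for k in np.unique(n_err):
        rows = np.flatnonzero(n_err == k)
        # k distinct positions per read via partial argsort of random keys
        keys = rng.random((len(rows), L))
        positions = np.argpartition(keys, k, axis=1)[:, :k]
        shifts = rng.integers(1, 4, size=positions.shape).astype(np.uint8)
        for col in range(k):
            idx = positions[:, col]
            out[rows, idx] = (out[rows, idx] + shifts[:, col]) % 4
    return out


def simulate_library(
    transcriptome: Sequence[TranscriptRecord],
    manifest: SimulationManifest,
    condition: str,
    abundances: pd.DataFrame | None = None,
) -> tuple[list[TagObservation], pd.DataFrame]:
    """Draw one SAGE library of tallied tag observations plus its truth.

    Tags are drawn multinomially from the condition's true TPM vector;
    each read independently acquires substitution errors at the per-base
    rate.  The truth table records true TPM, planted effect, realised FC
    and the error-free draw count per gene.
    """
    if condition not in ("control", "treated"):
        raise ValueError(f"condition must be control or treated, got {condition!r}")
    if abundances is None:
        abundances = simulate_abundances(manifest)
    db = extract_virtual_tags(transcriptome, manifest.tag_length)
    gene_tag = {}
    for entry in db:
        if not entry.ambiguous:
            (gene,) = entry.gene_ids
            gene_tag[gene] = entry.tag_sequence

    genes = [g for g in abundances.index if g in gene_tag]
    probs = abundances.loc[genes, f"tpm_{condition}"].to_numpy() / 1e6
    probs = probs / probs.sum()
    rng = manifest.rng("library", salt=1 if condition == "control" else 2)
    draws = rng.multinomial(manifest.n_tags_per_library, probs)

    L = manifest.tag_length
    p_err_read = 1.0 - (1.0 - manifest.per_base_error_rate) ** L
    n_err_reads = rng.binomial(draws, p_err_read)
    clean = draws - n_err_reads

    tally: dict[str, int] = {}
    for g, c in zip(genes, clean):
        if c > 0:
            tally[gene_tag[g]] = tally.get(gene_tag[g], 0) + int(c)

    total_err = int(n_err_reads.sum())
    if total_err:
        from .quantify import _encode

        src = np.repeat(np.arange(len(genes)), n_err_reads)
        tag_codes = _encode([gene_tag[g] for g in genes], L)
        mutated = _mutate_tags(rng, tag_codes[src], manifest.per_base_error_rate)
        as_bytes = (mutated + np.uint8(0)).copy()
        lut = np.zeros(4, dtype=np.uint8)
        for b, code in zip(b"ACGT", range(4)):
            lut[code] = b
        seqs = lut[as_bytes].view(f"S{L}").ravel()
        uniq, counts = np.unique(seqs, return_counts=True)
        for s, c in zip(uniq, counts):
            key = s.decode()
            tally[key] = tally.get(key, 0) + int(c)

    observations = [TagObservation(t, c) for t, c in sorted(tally.items())]
    truth = abundances.copy()
    truth["true_count"] = pd.Series(dict(zip(genes, draws.astype(int))))
    truth["true_count"] = truth["true_count"].fillna(0).astype(int)
    truth["condition"] = condition
    return observations, truth


def write_library_fastq(
    observations: Sequence[TagObservation], path: str | Path, read_length: int | None = None
) -> None:
    """Expand tallied tags into FASTQ reads (constant Q40 qualities).

    Intended for small libraries; reads are the bare tag unless
    ``read_length`` asks for random 3' padding.
    """
    rng = np.random.default_rng(0)
    with Path(path).open("w") as fh:
        i = 0
        for obs in observations:
            for _ in range(obs.count):
                i += 1
                seq = obs.tag_sequence
                if read_length and read_length > len(seq):
                    pad = _random_seq(rng, read_length - len(seq)).tobytes().decode()
                    seq = seq + pad
                fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Gene sets with planted enrichment


def simulate_gene_sets(
    gene_universe: Sequence[str],
    de_list: Sequence[str],
    n_sets: int = 20,
    set_size: int = 100,
    planted: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[GeneSet], pd.DataFrame]:
    """Random gene sets, some with planted over-representation.

    A planted fold ``f`` makes the fraction of set members drawn from the
    DE list equal ``f * len(de)/len(universe)``, so the set's expected
    fold enrichment against that DE list is ``f``.  Unplanted sets are
    uniform draws (expected enrichment 1).
    """
    rng = np.random.default_rng([seed, _STREAMS["sets"]])
    universe = sorted(set(gene_universe))
    de = sorted(set(de_list))
    non_de = sorted(set(universe) - set(de))
    planted = dict(planted or {})
    base_rate = len(de) / len(universe)

    sets = []
    truth_rows = []
    for i in range(1, n_sets + 1):
        set_id = f"SET{i:04d}"
        fold = planted.get(set_id, 1.0)
        frac_de = min(fold * base_rate, 1.0)
        n_de_members = int(round(set_size * frac_de))
        n_de_members = min(n_de_members, len(de))
        n_other = set_size - n_de_members
        if fold == 1.0:
            members = rng.choice(universe, size=set_size, replace=False)
        else:
            members = np.concatenate(
                [
                    rng.choice(de, size=n_de_members, replace=False),
                    rng.choice(non_de, size=n_other, replace=False),
                ]
            )
        sets.append(GeneSet(set_id, f"simulated set {i}", frozenset(map(str, members))))
        truth_rows.append(
            {"set_id": set_id, "planted_fold": fold, "n_de_members": n_de_members}
        )
    return sets, pd.DataFrame(truth_rows).set_index("set_id")


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct(
    manifest: SimulationManifest,
    true_log2_fc: Mapping[str, float],
    n_individuals: int = 9,
    n_controls: int = 6,
    references: Sequence[str] = ("rnf7", "rplp2", "rpl13a"),
    individual_sd: float = 0.0,
    label: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format Ct table for target and reference genes plus truth.

    Control samples sit at per-gene baselines; treated samples shift the
    target down by its true log2 FC (one cycle per doubling), optionally
    jittered per individual by ``individual_sd`` (biological variation).
    Reference genes have true FC 0 everywhere.  Technical noise of
    ``ct_noise_sd`` cycles applies to every replicate independently.
    """
    rng = manifest.rng("ct", salt=zlib.crc32(label.encode()) % (2**31))
    genes = sorted(true_log2_fc)
    all_genes = genes + [r for r in references if r not in genes]
    baselines = {
        g: float(rng.uniform(*manifest.ct_baseline_range)) for g in all_genes
    }
    rows = []
    truth_rows = []
    samples = [("control", f"C{i+1}") for i in range(n_controls)] + [
        ("treated", f"S{i+1}") for i in range(n_individuals)
    ]
    for group, sample in samples:
        for g in all_genes:
            shift = 0.0
            if group == "treated" and g in true_log2_fc:
                shift = true_log2_fc[g]
                if individual_sd > 0:
                    shift += float(rng.normal(0.0, individual_sd))
            if group == "treated" and g in true_log2_fc:
                truth_rows.append(
                    {"gene": g, "sample": sample, "true_log2_fc": shift}
                )
            for rep in range(1, manifest.ct_replicates + 1):
                noise = float(rng.normal(0.0, manifest.ct_noise_sd)) if manifest.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": g,
                        "sample": sample,
                        "group": group,
                        "replicate": rep,
                        "ct": baselines[g] - shift + noise,
                    }
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return table, truth


def ddct_standard_error(
    manifest: SimulationManifest,
    n_individuals: int,
    n_controls: int,
    n_references: int,
) -> float:
    """Analytic SE of the panel-mean -ddCt under the technical noise model.

    Per individual, Var(-ddCt) combines the treated sample's target and
    reference noise with the shared control-group baseline; averaging
    over individuals shrinks only the treated part.
    """
    var_rep = manifest.ct_noise_sd**2 / manifest.ct_replicates
    per_sample = var_rep * (1.0 + 1.0 / n_references)
    return float(np.sqrt(per_sample / n_individuals + per_sample / n_controls))
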