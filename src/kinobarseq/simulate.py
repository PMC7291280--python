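"""Synthetic Bar-seq screens with known ground truth.

Emulates the pooled toxicity-modifier screen end to end: a barcoded
deletion pool with log-normal baseline abundances shared across kinase
experiments, per-kinase planted suppressors (abundance up 2^effect) and
enhancers (down 2^effect), multinomial read sampling at a fixed sequencing
depth per kinase, and full amplicon reads assembled from each strain's
UPTAG and each kinase's indexing-tag pair.  Every stage of the analysis
pipeline can therefore be checked against the generator's truth tables
without any external data.
"""

from __future__ import annotations

import gzip
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
import yaml

from .catalog import BarcodeCatalog, DeletionStrain, SampleSheet
from .datasets import TOXIC_KINASES
from .demux import CountMatrix, ReadLayout, DEFAULT_LAYOUT, revcomp
from .screen import ENHANCER, NON_MODIFIER, SUPPRESSOR

NEUTRAL = "neutral"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_BARCODE_SEPARATION = 3  # minimum pairwise Hamming distance among UPTAGs


@dataclass
class SimConfig:
    """Study conditions of a simulated screen.

    Defaults are a desk-scale screen (500 strains, 5 kinase experiments);
    the full-scale pool is 4,653 strains against 28 kinases.  Effects are
    multiplicative on abundance: a planted suppressor's relative abundance
    is multiplied by 2**effect_log2fc, an enhancer's divided by it.
    ``abundance_dispersion`` is the standard deviation of baseline log2
    abundance across strains (drawn once, shared by all experiments).
    """

    n_strains: int = 500
    n_kinases: int = 5
    reads_per_kinase: int = 100_000
    frac_suppressors: float = 0.02
    frac_enhancers: float = 0.01
    effect_log2fc: float = 2.0
    abundance_dispersion: float = 0.5
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_strains, self.n_kinases, self.reads_per_kinase) <= 0:
            raise ValueError("n_strains, n_kinases and reads_per_kinase must be positive")
        for f in (self.frac_suppressors, self.frac_enhancers):
            if not 0.0 <= f <= 1.0:
                raise ValueError("modifier fractions must lie in [0, 1]")
        if self.frac_suppressors + self.frac_enhancers > 1.0:
            raise ValueError("modifier fractions must sum to at most 1")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class ScreenTruth:
    """Ground truth of one simulated screen.

    labels : DataFrame (strains × kinases) of suppressor/enhancer/neutral.
    expected_abundance : DataFrame of per-kinase relative abundances
        (each column sums to 1).
    counts : DataFrame of emitted read counts (each column sums to
        reads_per_kinase).
    """

    def __init__(
        self,
        labels: pd.DataFrame,
        expected_abundance: pd.DataFrame,
        counts: pd.DataFrame,
        config: SimConfig,
    ):
        self.labels = labels
        self.expected_abundance = expected_abundance
        self.counts = counts
        self.config = config

    @property
    def strain_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.counts.columns)

    def count_matrix(self) -> CountMatrix:
        """Emitted counts as a CountMatrix (the demux oracle)."""
        return CountMatrix(self.counts.copy())

    def planted(self, label: str) -> set[tuple[str, str]]:
        """Set of (strain_id, kinase) cells planted with the given label."""
        mask = self.labels == label
        return {
            (s, k)
            for s in self.labels.index
            for k in self.labels.columns
            if mask.at[s, k]
        }

    def to_tsv(self, path: str | Path) -> None:
        long = pd.DataFrame(
            {
                "strain_id": np.repeat(self.strain_ids, len(self.kinases)),
                "kinase": self.kinases * len(self.strain_ids),
                "label": self.labels.values.ravel(),
                "expected_abundance": self.expected_abundance.values.ravel(),
                "reads": self.counts.values.ravel(),
            }
        )
        long.to_csv(path, sep="\t", index=False)


def _random_distinct_barcodes(
    rng: np.random.Generator, n: int, length: int, min_dist: int
) -> np.ndarray:
    """n random barcodes (as a base-code matrix) with pairwise Hamming ≥ min_dist."""
    accepted = np.empty((n, length), dtype=np.uint8)
    got = 0
    budget = 200 * n + 1000
    while got < n:
        if budget <= 0:
            raise RuntimeError(
                f"could not draw {n} barcodes at pairwise distance {min_dist}"
            )
        budget -= 1
        cand = rng.integers(0, 4, size=length, dtype=np.uint8)
        if got and int((accepted[:got] != cand).sum(axis=1).min()) < min_dist:
            continue
        accepted[got] = cand
        got += 1
    return accepted


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _kinase_names(n: int) -> list[str]:
    names = list(TOXIC_KINASES[:n])
    names += [f"KIN{i:03d}" for i in range(len(names), n)]
    return names


def simulate_screen(cfg: SimConfig) -> tuple[ScreenTruth, BarcodeCatalog, SampleSheet]:
    """Draw one screen: pool, tags, planted modifiers and read counts.

    All randomness flows from ``cfg.seed`` through a single generator in a
    fixed draw order, so identical configs give byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)

    bc_codes = _random_distinct_barcodes(rng, cfg.n_strains, 20, _MIN_BARCODE_SEPARATION)
    strains = [
        DeletionStrain(f"strain{i:04d}", f"ygene{i:04d}", _codes_to_str(bc_codes[i]))
        for i in range(cfg.n_strains)
    ]
    catalog = BarcodeCatalog(strains)

    kinases = _kinase_names(cfg.n_kinases)
    pairs: dict[str, tuple[str, str]] = {}
    seen: set[tuple[str, str]] = set()
    for kinase in kinases:
        while True:
            fwd = _codes_to_str(rng.integers(0, 4, size=6, dtype=np.uint8))
            rev = _codes_to_str(rng.integers(0, 4, size=6, dtype=np.uint8))
            if (fwd, rev) not in seen:
                seen.add((fwd, rev))
                pairs[kinase] = (fwd, rev)
                break
    sheet = SampleSheet(pairs)

    base_log2 = rng.normal(0.0, cfg.abundance_dispersion, size=cfg.n_strains)

    u = rng.random(size=(cfg.n_strains, cfg.n_kinases))
    sup = u < cfg.frac_suppressors
    enh = (~sup) & (u < cfg.frac_suppressors + cfg.frac_enhancers)
    labels = np.full((cfg.n_strains, cfg.n_kinases), NEUTRAL, dtype=object)
    labels[sup] = SUPPRESSOR
    labels[enh] = ENHANCER

    log2_ab = base_log2[:, None] + cfg.effect_log2fc * (
        sup.astype(float) - enh.astype(float)
    )
    ab = np.exp2(log2_ab)
    probs = ab / ab.sum(axis=0, keepdims=True)

    counts = np.empty((cfg.n_strains, cfg.n_kinases), dtype=np.int64)
    for k in range(cfg.n_kinases):
        counts[:, k] = rng.multinomial(cfg.reads_per_kinase, probs[:, k])

    index = catalog.strain_ids
    truth = ScreenTruth(
        labels=pd.DataFrame(labels, index=index, columns=kinases),
        expected_abundance=pd.DataFrame(probs, index=index, columns=kinases),
        counts=pd.DataFrame(counts, index=index, columns=kinases),
        config=cfg,
    )
    return truth, catalog, sheet


def _assemble_template(
    uptag: str, fwd_tag: str, rev_tag: str, layout: ReadLayout
) -> str:
    return (
        "G" + fwd_tag + layout.fwd_anchor + uptag
        + revcomp(layout.rev_anchor) + revcomp(rev_tag) + "G"
    )


def iter_reads(
    truth: ScreenTruth,
    catalog: BarcodeCatalog,
    sheet: SampleSheet,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) for every emitted read, deterministically.

    Substitution errors are applied i.i.d. per base at the configured
    ``seq_error_rate`` from a stream derived from the screen seed, so a
    given truth always emits the same reads.
    """
    cfg = truth.config
    err_rng = np.random.default_rng([cfg.seed, 1])
    for strain in catalog:
        fwd_by_kinase = truth.counts.loc[strain.strain_id]
        for kinase in truth.kinases:
            n = int(fwd_by_kinase[kinase])
            if n == 0:
                continue
            fwd_tag, rev_tag = sheet[kinase]
            template = _assemble_template(strain.uptag, fwd_tag, rev_tag, layout)
            prefix = f"sim:{kinase}:{strain.strain_id}"
            if cfg.seq_error_rate == 0.0:
                for i in range(n):
                    yield f"{prefix}:{i}", template
            else:
                codes = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
                codes = np.searchsorted(_BASES, codes).astype(np.uint8)
                block = np.tile(codes, (n, 1))
                mask = err_rng.random(block.shape) < cfg.seq_error_rate
                n_err = int(mask.sum())
                if n_err:
                    shift = err_rng.integers(1, 4, size=n_err, dtype=np.uint8)
                    block[mask] = (block[mask] + shift) % 4
                seqs = _BASES[block]
                for i in range(n):
                    yield f"{prefix}:{i}", seqs[i].tobytes().decode("ascii")


def emit_fastq(
    truth: ScreenTruth,
    catalog: BarcodeCatalog,
    sheet: SampleSheet,
    path: str | Path | IO[str],
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> int:
    """Write the simulated reads as FASTQ (plain or .gz); returns read count.

    Quality is a constant 'I' per base: base-quality modelling is out of
    scope for this generator.
    """
    n = 0

    def _write(fh: IO[str]) -> int:
        written = 0
        for name, seq in iter_reads(truth, catalog, sheet, layout):
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            written += 1
        return written

    if hasattr(path, "write"):
        n = _write(path)  # type: ignore[arg-type]
    else:
        p = Path(path)
        opener = gzip.open if p.suffix == ".gz" else open
        with opener(p, "wt") as fh:
            n = _write(fh)
    return n


def recovery_report(calls: pd.DataFrame, truth: ScreenTruth) -> pd.DataFrame:
    """Precision/recall of pipeline calls against planted modifiers.

    One row per modifier class with the planted, called and recovered cell
    counts; recall (or precision) is NaN when nothing was planted (or
    called), rather than a fabricated 0 or 1.
    """
    rows = []
    for label in (SUPPRESSOR, ENHANCER):
        planted = truth.planted(label)
        called = {
            (r.strain_id, r.kinase)
            for r in calls[calls["label"] == label].itertuples(index=False)
        }
        hit = planted & called
        rows.append(
            {
                "label": label,
                "n_planted": len(planted),
                "n_called": len(called),
                "n_recovered": len(hit),
                "recall": len(hit) / len(planted) if planted else np.nan,
                "precision": len(hit) / len(called) if called else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def null_tail_fraction(calls: pd.DataFrame) -> float:
    """Fraction of all calls beyond the threshold (|Z| > tau) in either tail."""
    return float((calls["label"] != NON_MODIFIER).mean())
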