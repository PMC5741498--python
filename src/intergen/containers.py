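"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountExperiment:
    """A contig x sample read-count table with the metadata needed for
    normalisation and spike-in QC.

    Attributes
    ----------
    counts : DataFrame
        Non-negative integer matrix, contigs (incl. spike-in rows) x samples.
    contig_length : Series
        Length in bp per contig; >= 1 everywhere.
    mapped_total : Series
        Mapped reads per sample (supplied metadata; by convention excludes
        spike-mapped reads, see ``normqc``).
    is_spike : Series
        Boolean flag per contig marking synthetic spike-in controls.
    spike_expected : Series
        Expected input concentration (arbitrary units) for spike rows,
        NaN for biological contigs.
    """

    counts: pd.DataFrame
    contig_length: pd.Series
    mapped_total: pd.Series
    is_spike: pd.Series
    spike_expected: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        idx = self.counts.index
        if self.spike_expected is None:
            self.spike_expected = pd.Series(np.nan, index=idx)
        for name, s in (
            ("contig_length", self.contig_length),
            ("is_spike", self.is_spike),
            ("spike_expected", self.spike_expected),
        ):
            if not s.index.equals(idx):
                raise ValueError(f"{name} index does not match counts rows")
        if not self.mapped_total.index.equals(self.counts.columns):
            raise ValueError("mapped_total index does not match counts columns")
        if (self.contig_length < 1).any():
            raise ValueError("contig lengths must be >= 1")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        has_exp = self.spike_expected.notna()
        if not (has_exp == self.is_spike.astype(bool)).all():
            raise ValueError("spike_expected must be present exactly for spike rows")

    @property
    def contigs(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def biological(self) -> "CountExperiment":
        """The experiment restricted to non-spike contigs."""
        keep = ~self.is_spike.astype(bool)
        return CountExperiment(
            counts=self.counts.loc[keep],
            contig_length=self.contig_length.loc[keep],
            mapped_total=self.mapped_total,
            is_spike=self.is_spike.loc[keep],
            spike_expected=self.spike_expected.loc[keep],
        )

    def spikes(self) -> "CountExperiment":
        keep = self.is_spike.astype(bool)
        return CountExperiment(
            counts=self.counts.loc[keep],
            contig_length=self.contig_length.loc[keep],
            mapped_total=self.mapped_total,
            is_spike=self.is_spike.loc[keep],
            spike_expected=self.spike_expected.loc[keep],
        )

    def write_dir(self, outdir) -> None:
        """Write counts + per-contig metadata as TSV into ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="contig_id")
        meta = pd.DataFrame(
            {
                "length": self.contig_length,
                "is_spike": self.is_spike.astype(bool),
                "spike_expected": self.spike_expected,
            }
        )
        meta.to_csv(outdir / "contigs.tsv", sep="\t", index_label="contig_id")
        self.mapped_total.rename("mapped_total").to_csv(
            outdir / "mapped_total.tsv", sep="\t", index_label="sample_id"
        )

    @classmethod
    def read_dir(cls, indir) -> "CountExperiment":
        from pathlib import Path

        indir = Path(indir)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="contig_id")
        meta = pd.read_csv(indir / "contigs.tsv", sep="\t", index_col="contig_id")
        mapped = pd.read_csv(indir / "mapped_total.tsv", sep="\t", index_col="sample_id")[
            "mapped_total"
        ]
        return cls(
            counts=counts,
            contig_length=meta["length"],
            mapped_total=mapped,
            is_spike=meta["is_spike"].astype(bool),
            spike_expected=meta["spike_expected"],
        )


@dataclass
class ExpressionMatrix:
    """A contig x sample real-valued expression matrix with provenance."""

    values: pd.DataFrame
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")


@dataclass
class PeakTable:
    """An LC-MS peak table: mass signal x sample intensities with m/z,
    retention time and ionisation mode per signal."""

    intensity: pd.DataFrame  # signals x samples, >= 0
    mz: pd.Series
    rt: pd.Series
    ion_mode: pd.Series  # 'positive' | 'negative'

    def __post_init__(self) -> None:
        idx = self.intensity.index
        for name, s in (("mz", self.mz), ("rt", self.rt), ("ion_mode", self.ion_mode)):
            if not s.index.equals(idx):
                raise ValueError(f"{name} index does not match intensity rows")
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        for mode in self.ion_mode.unique():
            sub = idx[self.ion_mode == mode]
            if sub.has_duplicates:
                raise ValueError(f"duplicate signal ids within mode {mode}")

    @property
    def signals(self) -> pd.Index:
        return self.intensity.index

    @property
    def samples(self) -> pd.Index:
        return self.intensity.columns

    def select_mode(self, mode: str) -> "PeakTable":
        keep = self.ion_mode == mode
        return PeakTable(
            intensity=self.intensity.loc[keep],
            mz=self.mz.loc[keep],
            rt=self.rt.loc[keep],
            ion_mode=self.ion_mode.loc[keep],
        )

    def to_csv(self, path) -> None:
        out = pd.concat(
            [self.mz.rename("mz"), self.rt.rename("rt"), self.ion_mode.rename("mode"), self.intensity],
            axis=1,
        )
        out.to_csv(path, index_label="signal_id")

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        df = pd.read_csv(path, index_col="signal_id")
        return cls(
            intensity=df.drop(columns=["mz", "rt", "mode"]),
            mz=df["mz"],
            rt=df["rt"],
            ion_mode=df["mode"],
        )
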