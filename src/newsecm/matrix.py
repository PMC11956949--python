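"""Protein-group intensity matrices and their on-disk format.

The central container is :class:`IntensityMatrix`: a proteins x samples
table of raw label-free quantification (LFQ) intensities, where a zero
means the protein group was not observed in that run, together with
per-protein metadata (accession, gene symbol, organism of origin) and
per-sample metadata (culture model, metabolic-label treatment, and
whether the run is an input lysate or a streptavidin eluate).

On disk the matrix is a tab-delimited text file whose header row is
``Accession  Gene  Organism  <sample id> ...``; sample metadata travels
in a separate CSV keyed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANISMS = ("human", "rat", "contaminant")
MODELS = ("dECM-tumor", "tumoroid")
TREATMENTS = ("GalNAz", "vehicle")
FRACTIONS = ("input", "eluate")

PROTEIN_COLUMNS = ("gene", "organism")
SAMPLE_COLUMNS = ("model", "treatment", "fraction")


@dataclass
class IntensityMatrix:
    """Raw LFQ intensities with protein and sample annotations.

    Parameters
    ----------
    values
        DataFrame of nonnegative finite intensities, indexed by protein
        accession with one column per sample id. Zero encodes
        "not observed".
    proteins
        DataFrame indexed by accession with columns ``gene`` and
        ``organism`` (one of ``human``/``rat``/``contaminant``).
    samples
        DataFrame indexed by sample id with columns ``model``,
        ``treatment`` and ``fraction``.
    """

    values: pd.DataFrame
    proteins: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein accessions")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not self.values.index.equals(self.proteins.index):
            self.proteins = self.proteins.loc[self.values.index]
        if not self.values.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if (arr < 0).any():
            raise ValueError("intensities must be nonnegative")
        bad = set(self.proteins["organism"]) - set(ORGANISMS)
        if bad:
            raise ValueError(f"unknown organism tags: {sorted(bad)}")

    # -- convenience selectors -------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, *, model=None, treatment=None, fraction=None,
                       ids=None) -> "IntensityMatrix":
        """Subset samples by metadata fields and/or explicit ids."""
        keep = pd.Series(True, index=self.samples.index)
        if model is not None:
            keep &= self.samples["model"] == model
        if treatment is not None:
            keep &= self.samples["treatment"] == treatment
        if fraction is not None:
            keep &= self.samples["fraction"] == fraction
        if ids is not None:
            keep &= self.samples.index.isin(list(ids))
        cols = self.samples.index[keep]
        return IntensityMatrix(self.values[cols], self.proteins.copy(),
                               self.samples.loc[cols])

    def select_proteins(self, *, organism=None, accessions=None) -> "IntensityMatrix":
        keep = pd.Series(True, index=self.proteins.index)
        if organism is not None:
            keep &= self.proteins["organism"] == organism
        if accessions is not None:
            keep &= self.proteins.index.isin(list(accessions))
        idx = self.proteins.index[keep]
        return IntensityMatrix(self.values.loc[idx], self.proteins.loc[idx],
                               self.samples.copy())

    # -- I/O --------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the tab-delimited intensity table (no sample metadata)."""
        out = pd.concat([self.proteins[list(PROTEIN_COLUMNS)], self.values],
                        axis=1)
        out.index.name = "Accession"
        out = out.rename(columns={"gene": "Gene", "organism": "Organism"})
        out.to_csv(path, sep="\t")

    def sample_metadata_to_csv(self, path) -> None:
        out = self.samples.copy()
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def from_tsv(cls, path, sample_metadata) -> "IntensityMatrix":
        """Read the tab-delimited table plus a sample-metadata CSV.

        ``sample_metadata`` is a path to a CSV with columns
        ``sample_id, model, treatment, fraction``, or an equivalent
        DataFrame indexed by sample id.
        """
        table = pd.read_csv(path, sep="\t", index_col=0)
        proteins = table[["Gene", "Organism"]].rename(
            columns={"Gene": "gene", "Organism": "organism"})
        values = table.drop(columns=["Gene", "Organism"])
        if isinstance(sample_metadata, (str, bytes)) or hasattr(sample_metadata, "__fspath__"):
            samples = pd.read_csv(sample_metadata, index_col="sample_id")
        else:
            samples = sample_metadata
        return cls(values, proteins, samples)


@dataclass
class NormalizedMatrix(IntensityMatrix):
    """An IntensityMatrix after sum normalization.

    Carries the per-sample scale factors that were applied and a
    human-readable descriptor of each normalization scope (which samples
    were normalized together, over which protein subset the sums ran).
    """

    scale_factors: pd.Series = field(default_factory=pd.Series)
    scopes: dict = field(default_factory=dict)

    def scale_factors_to_csv(self, path) -> None:
        out = self.scale_factors.rename("scale_factor").to_frame()
        out.index.name = "sample_id"
        out["scope"] = [next((name for name, ids in self.scopes.items()
                              if s in ids["samples"]), "")
                        for s in out.index]
        out.to_csv(path)
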