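"""Gene-by-sample TPM matrices for the three-timepoint diel sampling design.

The design samples RNA at dusk of day 3 and at dawn and dusk of day 4 of a
12 h light / 12 h dark regime, with R >= 2 replicates per timepoint. On disk a
matrix is a TSV whose first column is ``gene_id`` and whose remaining columns
are named ``<condition>:<timepoint>:<replicate>`` with timepoint in
{dusk3, dawn4, dusk4}.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

TIMEPOINTS: tuple[str, ...] = ("dusk3", "dawn4", "dusk4")


@dataclass
class DielMatrix:
    """TPM table indexed by gene, with (timepoint, replicate) columns.

    Attributes
    ----------
    tpm : DataFrame with unique ``gene_id`` index and a two-level column
        MultiIndex ``(timepoint, replicate)``; values are nonnegative TPMs.
    condition : free-text condition label (strain / light regime).
    """

    tpm: pd.DataFrame
    condition: str = "wt"

    def __post_init__(self) -> None:
        df = self.tpm
        if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 2:
            raise InvalidInputError("tpm columns must be a (timepoint, replicate) MultiIndex")
        tps = set(df.columns.get_level_values(0))
        if tps != set(TIMEPOINTS):
            raise InvalidInputError(
                f"matrix must contain exactly the timepoints {TIMEPOINTS}, got {sorted(tps)}"
            )
        rep_counts = {tp: df[tp].shape[1] for tp in TIMEPOINTS}
        if len(set(rep_counts.values())) != 1:
            raise InvalidInputError(f"unequal replicate counts per timepoint: {rep_counts}")
        if self.n_replicates < 2:
            raise InvalidInputError("at least 2 replicates per timepoint are required")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise InvalidInputError(f"duplicated gene_id entries: {dups}")
        vals = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("non-finite TPM values present")
        if (vals < 0).any():
            g, c = np.argwhere(vals < 0)[0]
            raise InvalidInputError(
                f"negative TPM at gene {df.index[g]!r}, column {df.columns[c]}"
            )

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.tpm[TIMEPOINTS[0]].shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    def timepoint_values(self, timepoint: str) -> np.ndarray:
        """Replicate TPM values for one timepoint, shape (n_genes, R)."""
        return self.tpm[timepoint].to_numpy(dtype=float)

    def timepoint_means(self) -> pd.DataFrame:
        """Replicate-mean TPM per timepoint (genes x 3)."""
        return pd.DataFrame(
            {tp: self.tpm[tp].mean(axis=1) for tp in TIMEPOINTS}, index=self.tpm.index
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        flat = self.tpm.copy()
        flat.columns = [
            f"{self.condition}:{tp}:{rep}" for tp, rep in self.tpm.columns
        ]
        flat.index.name = "gene_id"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, mapping: dict[str, str] | None = None) -> "DielMatrix":
        """Read a matrix TSV written by :meth:`to_tsv`.

        ``mapping`` optionally renames external column headers to the canonical
        ``condition:timepoint:replicate`` form before parsing, so supplementary
        tables with other naming schemes can be ingested.
        """
        raw = pd.read_csv(path, sep="\t", dtype=str)
        if raw.columns[0] != "gene_id":
            raise InvalidInputError(f"{path}: first column must be 'gene_id'")
        raw = raw.set_index("gene_id")
        if mapping:
            raw = raw.rename(columns=mapping)
        if raw.index.has_duplicates:
            dups = raw.index[raw.index.duplicated()].unique().tolist()[:5]
            raise InvalidInputError(f"{path}: duplicated gene_id entries: {dups}")
        conditions: set[str] = set()
        cols: list[tuple[str, int]] = []
        for name in raw.columns:
            parts = str(name).split(":")
            if len(parts) != 3:
                raise InvalidInputError(
                    f"{path}: column {name!r} is not of the form condition:timepoint:rep"
                )
            cond, tp, rep = parts
            if tp not in TIMEPOINTS:
                raise InvalidInputError(f"{path}: unknown timepoint {tp!r} in column {name!r}")
            conditions.add(cond)
            cols.append((tp, int(rep)))
        if len(conditions) != 1:
            raise InvalidInputError(f"{path}: mixed conditions in one matrix: {sorted(conditions)}")
        values = np.empty(raw.shape, dtype=float)
        for j, name in enumerate(raw.columns):
            try:
                # numpy's conversion is correctly rounded, so write->read->write
                # is byte-identical; pandas' fast parser can be off by one ulp
                values[:, j] = raw[name].to_numpy(dtype=np.float64)
            except (ValueError, TypeError):
                col = pd.to_numeric(raw[name], errors="coerce")
                gene = raw.index[col.isna().to_numpy().nonzero()[0][0]]
                raise InvalidInputError(
                    f"{path}: non-numeric value at gene {gene!r}, column {name!r}"
                ) from None
            if np.isnan(values[:, j]).any():
                gene = raw.index[np.isnan(values[:, j]).nonzero()[0][0]]
                raise InvalidInputError(f"{path}: missing value at gene {gene!r}, column {name!r}")
        neg = np.argwhere(values < 0)
        if neg.size:
            g, c = neg[0]
            raise InvalidInputError(
                f"{path}: negative TPM at gene {raw.index[g]!r}, column {raw.columns[c]!r}"
            )
        df = pd.DataFrame(values, index=raw.index, columns=pd.MultiIndex.from_tuples(cols))
        # canonical order: dusk3, dawn4, dusk4, replicates ascending within each
        ordered = [
            (tp, rep)
            for tp in TIMEPOINTS
            for rep in sorted(r for t, r in cols if t == tp)
        ]
        df = df.loc[:, ordered]
        return cls(tpm=df, condition=next(iter(conditions)))


def build_matrix(
    log2_values: np.ndarray,
    gene_ids,
    n_replicates: int,
    condition: str = "wt",
) -> DielMatrix:
    """Assemble a DielMatrix from log2(TPM+1) values, shape (genes, 3, R).

    The timepoint axis follows :data:`TIMEPOINTS`. Values are converted back to
    TPM via ``2**x - 1`` and clipped at zero.
    """
    g, t, r = log2_values.shape
    if t != len(TIMEPOINTS) or r != n_replicates:
        raise InvalidInputError("log2_values must have shape (genes, 3, n_replicates)")
    tpm = np.clip(np.exp2(log2_values) - 1.0, 0.0, None)
    cols = pd.MultiIndex.from_product([TIMEPOINTS, range(1, n_replicates + 1)])
    flat = tpm.reshape(g, t * r)
    df = pd.DataFrame(flat, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    return DielMatrix(tpm=df, condition=condition)
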