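"""Readers, writers and the shared in-memory data model.

The central container is :class:`MethylationMatrix`: an ``n x m`` array of
methylation values (individuals in rows, probes in columns) together with
probe annotation (chromosome, base-pair position, gene, strand orientation)
and sample identifiers.  A ``scale_state`` tag tracks whether the values are
raw beta values in [0, 1], standardized (per-probe mean 0, variance 1), or
covariate-residualized.

On disk, matrices are stored probes-as-rows (the long dimension) with
individuals as columns; probe annotation uses an OSCA-style whitespace table
with columns chr, probe_id, bp, gene, orientation; relationship matrices use
GRM-style lower-triangle text triplets.  All formats are plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_ANNOT_COLUMNS = ["chr", "probe_id", "bp", "gene", "orientation"]
MWAS_COLUMNS = ["Chr", "Probe", "bp", "Gene", "Orientation", "b", "se", "p"]

VALID_SCALE_STATES = ("beta", "standardized", "residualized")


class AlignmentError(ValueError):
    """Sample or probe identifiers do not line up across files."""


class ValidationError(ValueError):
    """A container violates one of its structural invariants."""


@dataclass
class MethylationMatrix:
    """Individuals x probes methylation values with probe annotation.

    Parameters
    ----------
    values
        ``(n, m)`` float array. When ``scale_state == "beta"`` all entries
        must lie in [0, 1]; when ``"standardized"`` each probe has mean 0
        and variance 1 (population convention, divisor ``n``).
    probe_annot
        DataFrame with columns ``chr`` (strings "1".."22"), ``probe_id``,
        ``bp`` (1-based), ``gene``, ``orientation`` ("F"/"R"); one row per
        probe, in column order of ``values``.
    sample_ids
        Length-``n`` list of unique sample identifiers.
    scale_state
        One of ``"beta"``, ``"standardized"``, ``"residualized"``.
    """

    values: np.ndarray
    probe_annot: pd.DataFrame
    sample_ids: list[str]
    scale_state: str = "beta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.probe_annot) != m:
            raise ValidationError(
                f"{len(self.probe_annot)} annotation rows for {m} probes"
            )
        if self.scale_state not in VALID_SCALE_STATES:
            raise ValidationError(f"unknown scale_state {self.scale_state!r}")
        pids = self.probe_annot["probe_id"]
        if pids.duplicated().any():
            dups = pids[pids.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValidationError(
                "missing methylation values are not supported"
            )
        if self.scale_state == "beta":
            if self.values.size and (
                self.values.min() < 0 or self.values.max() > 1
            ):
                raise ValidationError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def probe_ids(self) -> np.ndarray:
        return self.probe_annot["probe_id"].to_numpy()

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        """Return a copy restricted to ``probe_ids`` (order preserved)."""
        idx = pd.Index(self.probe_annot["probe_id"])
        locs = idx.get_indexer(list(probe_ids))
        if (locs < 0).any():
            missing = [p for p, l in zip(probe_ids, locs) if l < 0]
            raise AlignmentError(f"probes not present: {missing[:5]}")
        return replace(
            self,
            values=self.values[:, locs].copy(),
            probe_annot=self.probe_annot.iloc[locs].reset_index(drop=True),
        )


@dataclass
class MwasTable:
    """Per-probe association results from one MWAS engine.

    ``table`` has columns Chr, Probe, bp, Gene, Orientation, b, se, p and is
    kept sorted by chromosome then position.  ``method`` tags the engine and
    ``lambda_gc`` carries the genomic inflation factor of the scan.
    """

    table: pd.DataFrame
    method: str
    lambda_gc: float = float("nan")
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in MWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"MWAS table missing columns {missing}")
        t = self.table.loc[:, MWAS_COLUMNS].copy()
        if len(t):
            p = t["p"].to_numpy(float)
            if (p <= 0).any() or (p > 1).any():
                raise ValidationError("p-values must lie in (0, 1]")
            if (t["se"].to_numpy(float) <= 0).any():
                raise ValidationError("standard errors must be positive")
            t = t.sort_values(
                ["Chr", "bp"],
                key=lambda s: s.astype(int) if s.name in ("Chr", "bp") else s,
                kind="mergesort",
            ).reset_index(drop=True)
        self.table = t


def validate_sample_table(samples: pd.DataFrame, sample_ids=None) -> None:
    """Check a sample table against the data-model contract.

    The table is a plain DataFrame with one row per individual, a
    ``sample_id`` column, a 0/1 ``status`` column, and whatever covariate
    columns the analysis uses (age, sex, smoking_score, batch,
    chip_position, cell-type proportions ...).
    """
    if "sample_id" not in samples.columns:
        raise ValidationError("sample table needs a 'sample_id' column")
    if "status" in samples.columns:
        st = samples["status"].to_numpy()
        if not np.isin(st, (0, 1)).all():
            raise ValidationError("status must be coded 0 (control) / 1 (case)")
    if samples["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample table")
    if sample_ids is not None:
        want = list(sample_ids)
        have = samples["sample_id"].tolist()
        if want != have:
            missing = sorted(set(want) - set(have))
            extra = sorted(set(have) - set(want))
            raise AlignmentError(
                "sample table does not align with matrix: "
                f"missing={missing[:5]} extra={extra[:5]}"
            )


# ---------------------------------------------------------------------------
# matrix / annotation round trip

_FLOAT_FMT = "%.12g"  # >= 10 significant digits survive the round trip


def write_methylation(
    M: MethylationMatrix,
    samples: pd.DataFrame,
    matrix_path,
    probe_annot_path,
    sample_path,
) -> None:
    """Write matrix (probes x individuals TSV), probe and sample annotation."""
    df = pd.DataFrame(
        M.values.T, index=M.probe_ids, columns=M.sample_ids
    )
    df.index.name = "probe_id"
    df.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT)
    M.probe_annot.loc[:, PROBE_ANNOT_COLUMNS].to_csv(
        probe_annot_path, sep="\t", index=False, header=False
    )
    samples.to_csv(sample_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_methylation(
    matrix_path, probe_annot_path, sample_path, scale_state: str = "beta"
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Read a methylation matrix bundle written by :func:`write_methylation`.

    Probe order follows the annotation file; sample order follows the matrix
    header.  Raises :class:`AlignmentError` when identifiers disagree and a
    parse error naming the offending cell for non-numeric values.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    try:
        mat = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            for i, v in enumerate(raw[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric value {v!r} at probe "
                        f"{raw.index[i]!r}, sample {col!r}"
                    ) from None
        raise
    if raw.isna().any().any():
        raise ValidationError("missing methylation values are not supported")
    annot = pd.read_csv(
        probe_annot_path,
        sep=r"\s+",
        header=None,
        names=PROBE_ANNOT_COLUMNS,
        dtype={"chr": str, "probe_id": str, "gene": str, "orientation": str},
    )
    if annot["probe_id"].duplicated().any():
        dup = annot.loc[annot["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"duplicate probe ids in annotation: {dup[:5]}")
    if set(annot["probe_id"]) != set(mat.index):
        missing = sorted(set(mat.index) - set(annot["probe_id"]))
        extra = sorted(set(annot["probe_id"]) - set(mat.index))
        raise AlignmentError(
            f"probe annotation mismatch: missing={missing[:5]} "
            f"extra={extra[:5]}"
        )
    mat = mat.loc[annot["probe_id"]]
    samples = pd.read_csv(sample_path, sep="\t")
    samples["sample_id"] = samples["sample_id"].astype(str)
    validate_sample_table(samples, sample_ids=list(mat.columns))
    M = MethylationMatrix(
        values=mat.to_numpy().T,
        probe_annot=annot,
        sample_ids=list(mat.columns),
        scale_state=scale_state,
    )
    return M, samples


def write_mwas(result: MwasTable, path) -> None:
    """Write an MWAS table as TSV with p in scientific notation.

    A comment header carries the engine tag and genomic inflation factor.
    """
    path = Path(path)
    t = result.table.copy()
    with open(path, "w") as fh:
        fh.write(f"# method={result.method}\tlambda={result.lambda_gc:.6g}\n")
        for note in result.notes:
            fh.write(f"# note={note}\n")
        fh.write("\t".join(MWAS_COLUMNS) + "\n")
        for row in t.itertuples(index=False):
            fh.write(
                f"{row.Chr}\t{row.Probe}\t{row.bp}\t{row.Gene}\t"
                f"{row.Orientation}\t{row.b:.6g}\t{row.se:.6g}\t{row.p:.6e}\n"
            )


def read_mwas(path) -> MwasTable:
    path = Path(path)
    method, lam, notes = "unknown", float("nan"), []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("method="):
                fields = dict(
                    kv.split("=", 1) for kv in body.split("\t") if "=" in kv
                )
                method = fields.get("method", method)
                lam = float(fields.get("lambda", "nan"))
            elif body.startswith("note="):
                notes.append(body.split("=", 1)[1])
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"Chr": str, "Probe": str})
    return MwasTable(table=t, method=method, lambda_gc=lam, notes=notes)


# ---------------------------------------------------------------------------
# GRM-style relationship-matrix text

def write_orm_text(A: np.ndarray, m_used: int, sample_ids, prefix) -> None:
    """Write an n x n relationship matrix as GRM-style text.

    ``<prefix>.orm`` holds lower-triangle rows ``i j m A_ij`` (1-based) and
    ``<prefix>.orm.id`` one sample id per line.
    """
    prefix = Path(prefix)
    n = A.shape[0]
    with open(f"{prefix}.orm", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{m_used}\t{A[i, j]:.12g}\n")
    with open(f"{prefix}.orm.id", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\n")


def read_orm_text(prefix) -> tuple[np.ndarray, int, list[str]]:
    prefix = Path(prefix)
    with open(f"{prefix}.orm.id") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    n = len(ids)
    A = np.zeros((n, n))
    m_used = 0
    with open(f"{prefix}.orm") as fh:
        for line in fh:
            si, sj, sm, sv = line.split()
            i, j = int(si) - 1, int(sj) - 1
            A[i, j] = A[j, i] = float(sv)
            m_used = int(sm)
    return A, m_used, ids
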