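"""Spectra and physiology table I/O.

Native exchange format is CSV in two dialects:

* ``wide`` — first column is ``wavelength``, one column per sample; the
  header row carries sample ids and an optional block of metadata rows
  (``group``, ``stage``, ``date``, ``pot``, ``replicate``) sits between
  the header and the numeric data.
* ``long`` — columns ``sample_id, wavelength, value`` plus optional
  metadata companion columns, one row per (sample, band).

Both dialects begin with a ``# kind=...`` comment recording whether the
values are reflectance (unitless fraction) or first-derivative
reflectance (per nm).  Values are emitted with 6 significant digits;
round trips are value-exact for inputs representable at that precision.
Reflectance may arrive on a percent scale (0-100); pass
``reflectance_scale="percent"`` to rescale on read — the canonical
internal scale is always the unit fraction.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

METADATA_KEYS = ("group", "stage", "date", "pot", "replicate")
INDICATORS = ("SPAD", "A", "gsw", "Ci", "FvpFmp", "qP", "qN")

#: indicators bounded to [0, 1] by definition
_UNIT_INTERVAL_INDICATORS = ("FvpFmp", "qP")

_VALUE_FMT = "%.6g"
_WL_FMT = "%.10g"

# reflectance sanity bounds: small calibration overshoot above 1 is
# tolerated, as is tiny numerical undershoot from smoothing filters
_REFLECTANCE_LO = -0.1
_REFLECTANCE_HI = 1.5


@dataclass
class Spectrum:
    """One sample's spectrum on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array of nm values, strictly increasing.
    values : reflectance (unitless fraction) or derivative reflectance
        (per nm), same length as ``wavelengths``.
    kind : ``"reflectance"`` or ``"first_derivative"``.
    metadata : per-sample annotations (``sample_id``, ``group`` CK/T,
        ``stage``, ``date``, ``pot``, ``replicate``).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise ValidationError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.values.size} values"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.kind not in ("reflectance", "first_derivative"):
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "reflectance" and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < _REFLECTANCE_LO or hi > _REFLECTANCE_HI:
                raise ValidationError(
                    f"reflectance values outside [{_REFLECTANCE_LO}, "
                    f"{_REFLECTANCE_HI}]: range [{lo:.4g}, {hi:.4g}]"
                )

    @property
    def sample_id(self) -> str:
        return str(self.metadata.get("sample_id", ""))

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SampleTable:
    """Aligned spectra matrix and physiology table for one data slice.

    ``spectra`` is a samples x bands DataFrame (index: sample ids,
    columns: wavelengths in nm); ``physiology`` holds one row per sample
    with indicator columns; ``metadata`` carries the per-sample
    annotations.  All three share the same index, in the same order.
    """

    spectra: pd.DataFrame
    physiology: pd.DataFrame
    metadata: pd.DataFrame
    kind: str = "reflectance"
    dropped_ids: tuple = ()

    def __post_init__(self):
        ids = list(self.spectra.index)
        if list(self.physiology.index) != ids or list(self.metadata.index) != ids:
            raise AlignmentError("spectra/physiology/metadata indices differ")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray(self.spectra.columns, dtype=float)

    @property
    def sample_ids(self) -> list:
        return list(self.spectra.index)

    def __len__(self) -> int:
        return len(self.spectra)

    def subset(self, ids: Sequence) -> "SampleTable":
        ids = list(ids)
        return SampleTable(
            self.spectra.loc[ids],
            self.physiology.loc[ids],
            self.metadata.loc[ids],
            kind=self.kind,
        )


def _as_stream(source) -> TextIO:
    if isinstance(source, str) and "\n" not in source:
        return open(source, "r", newline="")
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _fmt(value: float, fmt: str = _VALUE_FMT) -> str:
    return fmt % value


def _parse_kind(first_line: str) -> str:
    line = first_line.strip()
    if line.startswith("#") and "kind=" in line:
        return line.split("kind=", 1)[1].strip()
    raise FormatError("missing '# kind=...' header line")


def read_spectra_table(
    source, dialect: str = "wide", reflectance_scale: str = "fraction"
) -> list[Spectrum]:
    """Read spectra from a CSV stream, path, or literal text.

    Raises :class:`FormatError` on non-monotone or duplicated
    wavelengths and :class:`AlignmentError` on ragged grids.
    """
    if dialect not in ("wide", "long", "wide_csv", "long_csv"):
        raise FormatError(f"unknown dialect {dialect!r}")
    dialect = dialect.removesuffix("_csv")
    stream = _as_stream(source)
    rows = list(csv.reader(stream))
    if hasattr(stream, "close") and stream is not source:
        stream.close()
    if not rows:
        raise FormatError("empty input")
    kind = _parse_kind(",".join(rows[0]))
    rows = rows[1:]
    scale = 0.01 if reflectance_scale == "percent" else 1.0
    if reflectance_scale not in ("fraction", "percent"):
        raise FormatError(f"unknown reflectance scale {reflectance_scale!r}")
    if dialect == "wide":
        spectra = _read_wide(rows, kind, scale)
    else:
        spectra = _read_long(rows, kind, scale)
    grids = {tuple(s.wavelengths.tolist()) for s in spectra}
    if len(grids) > 1:
        raise AlignmentError("samples do not share a common wavelength grid")
    return spectra


def _check_grid(wavelengths: np.ndarray, context: str) -> None:
    d = np.diff(wavelengths)
    if np.any(d == 0):
        raise FormatError(f"duplicate wavelength in {context}")
    if np.any(d < 0):
        raise FormatError(f"non-monotone wavelengths in {context}")


def _read_wide(rows, kind, scale) -> list[Spectrum]:
    if not rows:
        raise FormatError("wide table has no header row")
    header = rows[0]
    sample_ids = header[1:]
    meta: dict[str, list[str]] = {}
    data_rows = []
    for row in rows[1:]:
        if not row or not row[0]:
            continue
        if row[0] in METADATA_KEYS:
            meta[row[0]] = row[1:]
        else:
            data_rows.append(row)
    if not sample_ids:
        return []
    try:
        wl = np.array([float(r[0]) for r in data_rows])
        vals = np.array(
            [[float(x) for x in r[1 : 1 + len(sample_ids)]] for r in data_rows]
        )
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed wide table row: {exc}") from exc
    _check_grid(wl, "wide table")
    spectra = []
    for j, sid in enumerate(sample_ids):
        md = {"sample_id": sid}
        for key, vals_row in meta.items():
            if j < len(vals_row) and vals_row[j] != "":
                md[key] = vals_row[j]
        v = vals[:, j] * scale if kind == "reflectance" else vals[:, j]
        spectra.append(Spectrum(wl, v, kind=kind, metadata=md))
    return spectra


def _read_long(rows, kind, scale) -> list[Spectrum]:
    if not rows:
        raise FormatError("long table has no header row")
    header = rows[0]
    try:
        i_sid = header.index("sample_id")
        i_wl = header.index("wavelength")
        i_val = header.index("value")
    except ValueError as exc:
        raise FormatError("long dialect needs sample_id,wavelength,value") from exc
    meta_cols = [(i, name) for i, name in enumerate(header) if name in METADATA_KEYS]
    per_sample: dict[str, dict] = {}
    for row in rows[1:]:
        if not row:
            continue
        sid = row[i_sid]
        rec = per_sample.setdefault(sid, {"wl": [], "val": [], "md": {"sample_id": sid}})
        try:
            rec["wl"].append(float(row[i_wl]))
            rec["val"].append(float(row[i_val]))
        except ValueError as exc:
            raise FormatError(f"malformed long table row: {exc}") from exc
        for i, name in meta_cols:
            if row[i] != "":
                rec["md"][name] = row[i]
    spectra = []
    for sid, rec in per_sample.items():
        wl = np.array(rec["wl"])
        _check_grid(wl, f"sample {sid!r}")
        v = np.array(rec["val"])
        if kind == "reflectance":
            v = v * scale
        spectra.append(Spectrum(wl, v, kind=kind, metadata=rec["md"]))
    return spectra


def write_spectra_table(
    spectra: Sequence[Spectrum], dialect: str = "wide", stream: TextIO | None = None
) -> str:
    """Write spectra as CSV text; inverse of :func:`read_spectra_table`."""
    dialect = dialect.removesuffix("_csv")
    if dialect not in ("wide", "long"):
        raise FormatError(f"unknown dialect {dialect!r}")
    kinds = {s.kind for s in spectra}
    if len(kinds) > 1:
        raise FormatError(f"mixed spectrum kinds {sorted(kinds)} in one table")
    kind = kinds.pop() if kinds else "reflectance"
    if len(spectra) > 1:
        grids = {tuple(s.wavelengths.tolist()) for s in spectra}
        if len(grids) > 1:
            raise AlignmentError("spectra do not share a grid")
    out = io.StringIO()
    out.write(f"# kind={kind}\n")
    writer = csv.writer(out, lineterminator="\n")
    if dialect == "wide":
        writer.writerow(["wavelength"] + [s.sample_id for s in spectra])
        present = [k for k in METADATA_KEYS if any(k in s.metadata for s in spectra)]
        for key in present:
            writer.writerow([key] + [str(s.metadata.get(key, "")) for s in spectra])
        if spectra:
            wl = spectra[0].wavelengths
            for i in range(wl.size):
                writer.writerow(
                    [_fmt(wl[i], _WL_FMT)] + [_fmt(s.values[i]) for s in spectra]
                )
    else:
        present = [
            k for k in METADATA_KEYS if any(k in s.metadata for s in spectra)
        ]
        writer.writerow(["sample_id", "wavelength", "value"] + present)
        for s in spectra:
            md = [str(s.metadata.get(k, "")) for k in present]
            for i in range(len(s)):
                writer.writerow(
                    [s.sample_id, _fmt(s.wavelengths[i], _WL_FMT), _fmt(s.values[i])]
                    + md
                )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_physiology_table(source) -> pd.DataFrame:
    """Read a physiology CSV (``sample_id`` plus indicator columns).

    Missing indicator columns are flagged in ``df.attrs["missing"]``,
    never imputed.  Negative values and out-of-range quantum yields
    raise :class:`ValidationError`.
    """
    stream = _as_stream(source)
    df = pd.read_csv(stream)
    if hasattr(stream, "close") and stream is not source:
        stream.close()
    if "sample_id" not in df.columns:
        raise FormatError("physiology table needs a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    present = [c for c in INDICATORS if c in df.columns]
    for col in present:
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValidationError(f"negative values in indicator {col}")
        if col in _UNIT_INTERVAL_INDICATORS and np.any(vals > 1 + 1e-9):
            raise ValidationError(f"{col} exceeds 1")
    df.attrs["missing"] = tuple(c for c in INDICATORS if c not in df.columns)
    return df


def write_physiology_table(df: pd.DataFrame, stream: TextIO | None = None) -> str:
    out = io.StringIO()
    df.to_csv(out, index=True, index_label="sample_id", float_format=_VALUE_FMT,
              lineterminator="\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def average_replicates(
    spectra: Sequence[Spectrum], by: Sequence[str] = ("group", "stage", "date", "pot")
) -> list[Spectrum]:
    """Average replicate scans per group of metadata keys.

    Mirrors the field protocol of recording the mean of repeated scans
    of one sample.  Members of a group must share grid and kind; the
    ``replicate`` field is cleared on the averaged spectra.
    """
    if not spectra:
        raise ValidationError("no spectra to average")
    groups: dict[tuple, list[Spectrum]] = {}
    order: list[tuple] = []
    for s in spectra:
        key = tuple(str(s.metadata.get(k, "")) for k in by)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    out = []
    for key in order:
        members = groups[key]
        grids = {tuple(m.wavelengths.tolist()) for m in members}
        kinds = {m.kind for m in members}
        if len(grids) > 1 or len(kinds) > 1:
            raise AlignmentError(f"replicate group {key} mixes grids or kinds")
        mean_vals = np.mean([m.values for m in members], axis=0)
        sids = {m.sample_id for m in members}
        md = {k: str(members[0].metadata.get(k, "")) for k in by
              if members[0].metadata.get(k, "") != ""}
        md["sample_id"] = sids.pop() if len(sids) == 1 else "|".join(
            str(v) for v in key if v != "")
        out.append(Spectrum(members[0].wavelengths, mean_vals,
                            kind=members[0].kind, metadata=md))
    return out


def spectra_to_frame(spectra: Sequence[Spectrum]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack spectra into (values frame, metadata frame), both indexed by id."""
    if not spectra:
        raise ValidationError("no spectra given")
    grids = {tuple(s.wavelengths.tolist()) for s in spectra}
    if len(grids) > 1:
        raise AlignmentError("spectra do not share a grid")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sample ids")
    values = pd.DataFrame(
        np.vstack([s.values for s in spectra]),
        index=ids,
        columns=spectra[0].wavelengths,
    )
    meta = pd.DataFrame(
        [{k: s.metadata.get(k, "") for k in METADATA_KEYS} for s in spectra],
        index=ids,
    )
    return values, meta


def validate_alignment(
    spectra: Sequence[Spectrum], physiology: pd.DataFrame
) -> SampleTable:
    """Intersect spectra and physiology by sample id into a SampleTable.

    Samples present on only one side are dropped and recorded in
    ``table.dropped_ids``; an empty intersection is an error.
    """
    values, meta = spectra_to_frame(spectra)
    spec_ids = list(values.index)
    phys_ids = set(str(i) for i in physiology.index)
    kept = [i for i in spec_ids if i in phys_ids]
    dropped = tuple(sorted((set(spec_ids) | phys_ids) - set(kept)))
    if not kept:
        raise AlignmentError("no common sample ids between spectra and physiology")
    return SampleTable(
        values.loc[kept],
        physiology.loc[kept],
        meta.loc[kept],
        kind=spectra[0].kind,
        dropped_ids=dropped,
    )
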