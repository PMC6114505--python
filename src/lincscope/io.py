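"""Reading and writing LINCS-style signature data.

Signature metadata travels as tab-separated tables shaped like the GEO
``sig_info`` files (one row per signature, columns for cell line,
perturbagen, dose, time and replicate count).  Z-score matrices travel as
GCT 1.3 text files or GCTX HDF5 containers with one row per landmark gene
and one column per signature.

Everything read here is canonicalized on the way in: doses to micromolar,
times to hours, perturbation type codes to the six standard categories
(control, ligand, poscon, compound, overexpression, shRNA).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six canonical perturbation categories.
CATEGORIES = ("control", "ligand", "poscon", "compound", "overexpression", "shRNA")

#: Sentinel returned by :func:`map_pert_category` for unrecognized codes.
UNKNOWN_CATEGORY = "unknown"

#: LINCS convention for "not applicable" in metadata files.
MISSING_SENTINEL = "-666"

# Published LINCS pert_type codes -> canonical category.
_PERT_TYPE_MAP = {
    "trt_cp": "compound",
    "trt_lig": "ligand",
    "trt_sh": "shRNA",
    "trt_sh.cgs": "shRNA",
    "trt_oe": "overexpression",
    "trt_oe.mut": "overexpression",
    "ctl_vehicle": "control",
    "ctl_vehicle.cns": "control",
    "ctl_vector": "control",
    "ctl_vector.cns": "control",
    "ctl_untrt": "control",
    "ctl_untrt.cns": "control",
    "trt_poscon": "poscon",
    "ctl_trt_poscon": "poscon",
    "trt_sh.css": "poscon",
}

# Dose units recognized by parse_dose, as multipliers to micromolar.
_UNIT_TO_UM = {
    "nm": 1e-3,
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,
    "mm": 1e3,
}

#: Canonical metadata column names, in output order.
METADATA_COLUMNS = (
    "sig_id",
    "cell_id",
    "pert_id",
    "pert_iname",
    "pert_category",
    "dose_um",
    "time_h",
    "n_replicates",
)

#: Default field-name dialect: GEO ``sig_info`` column names.
DEFAULT_DIALECT = {
    "sig_id": "sig_id",
    "cell_id": "cell_id",
    "pert_id": "pert_id",
    "pert_iname": "pert_iname",
    "pert_type": "pert_type",
    "dose": "pert_dose",
    "dose_unit": "pert_dose_unit",
    "time": "pert_time",
    "n_replicates": "distil_nsample",
}

_MANDATORY_FIELDS = ("sig_id", "cell_id", "pert_id", "pert_type", "time")


@dataclass
class SignatureMatrix:
    """A landmark-gene x signature matrix of differential-expression z-scores.

    Parameters
    ----------
    gene_ids
        Row identifiers (978 landmark genes in LINCS-shaped data).
    sig_ids
        Column identifiers; join keys against a metadata table's ``sig_id``.
    z
        Array of shape ``(len(gene_ids), len(sig_ids))``.
    """

    gene_ids: list[str]
    sig_ids: list[str]
    z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be a 2-D array")
        if self.z.shape != (len(self.gene_ids), len(self.sig_ids)):
            raise ValueError(
                f"matrix shape {self.z.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sig_ids)} signatures"
            )
        if len(set(self.sig_ids)) != len(self.sig_ids):
            raise ValueError("duplicate sig_ids in matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_signatures(self) -> int:
        return len(self.sig_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.gene_ids, columns=self.sig_ids)


def parse_dose(value, unit) -> float | None:
    """Canonicalize a dose to micromolar.

    Recognized units are nM, uM (also written um/µM/μM) and mM.  The LINCS
    missing sentinel ``-666``, empty values and non-numeric values yield
    ``None``; an unrecognized unit yields ``None`` with a logged warning.
    This function never raises.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text == MISSING_SENTINEL or text == f"{MISSING_SENTINEL}.0":
        return None
    try:
        magnitude = float(text)
    except ValueError:
        logger.warning("non-numeric dose %r treated as missing", value)
        return None
    if magnitude <= 0 or magnitude == -666.0:
        return None
    if unit is None or (isinstance(unit, float) and math.isnan(unit)):
        unit_text = ""
    else:
        unit_text = str(unit).strip().lower()
    if unit_text in ("", MISSING_SENTINEL):
        return None
    factor = _UNIT_TO_UM.get(unit_text)
    if factor is None:
        logger.warning("unrecognized dose unit %r treated as missing", unit)
        return None
    return magnitude * factor


def parse_time(value) -> float | None:
    """Canonicalize a treatment duration to hours; ``None`` when unusable.

    Accepts bare numbers and numbers with an ``h`` suffix ("24", "24 h",
    "24h").
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text.endswith("h"):
        text = text[:-1].strip()
    if text in ("", MISSING_SENTINEL):
        return None
    try:
        hours = float(text)
    except ValueError:
        return None
    if hours <= 0 or hours == -666.0:
        return None
    return hours


def map_pert_category(raw_code) -> str:
    """Map a LINCS ``pert_type`` code onto the six canonical categories.

    Unknown codes return :data:`UNKNOWN_CATEGORY` (never silently binned
    into a real category) with a logged warning.
    """
    if raw_code is None or (isinstance(raw_code, float) and math.isnan(raw_code)):
        logger.warning("missing pert_type code")
        return UNKNOWN_CATEGORY
    category = _PERT_TYPE_MAP.get(str(raw_code).strip())
    if category is None:
        logger.warning("unrecognized pert_type code %r", raw_code)
        return UNKNOWN_CATEGORY
    return category


def read_metadata(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a signature metadata TSV into the canonical schema.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Mapping from canonical field names (keys of
        :data:`DEFAULT_DIALECT`) to column names in the file.  Unspecified
        keys fall back to the GEO ``sig_info`` names.

    Returns
    -------
    DataFrame with columns :data:`METADATA_COLUMNS`.  Rows whose mandatory
    fields cannot be canonicalized (unmappable perturbation code,
    non-numeric time, duplicated sig_id) are dropped and the count logged.

    Raises
    ------
    ValueError
        If a mandatory column is absent from the file.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in _MANDATORY_FIELDS:
        if names[key] not in raw.columns:
            raise ValueError(
                f"mandatory metadata column {names[key]!r} (field {key!r}) "
                f"missing from {path}"
            )

    n_in = len(raw)
    out = pd.DataFrame(
        {
            "sig_id": raw[names["sig_id"]].str.strip(),
            "cell_id": raw[names["cell_id"]].str.strip(),
            "pert_id": raw[names["pert_id"]].str.strip(),
        }
    )
    if names["pert_iname"] in raw.columns:
        out["pert_iname"] = raw[names["pert_iname"]].str.strip()
    else:
        out["pert_iname"] = out["pert_id"]
    out["pert_category"] = raw[names["pert_type"]].map(map_pert_category)

    if names["dose"] in raw.columns and names["dose_unit"] in raw.columns:
        out["dose_um"] = [
            parse_dose(v, u)
            for v, u in zip(raw[names["dose"]], raw[names["dose_unit"]])
        ]
    elif names["dose"] in raw.columns:
        # dose column carrying canonical uM values with no unit column
        out["dose_um"] = [parse_dose(v, "um") for v in raw[names["dose"]]]
    else:
        out["dose_um"] = None
    out["dose_um"] = out["dose_um"].astype(float)

    out["time_h"] = raw[names["time"]].map(parse_time).astype(float)

    if names["n_replicates"] in raw.columns:
        reps = pd.to_numeric(raw[names["n_replicates"]], errors="coerce")
    elif "distil_id" in raw.columns:
        # sig_info convention: replicate profile ids joined with '|'
        reps = raw["distil_id"].map(lambda s: s.count("|") + 1 if s else np.nan)
    else:
        reps = pd.Series(1, index=raw.index)
    out["n_replicates"] = reps

    keep = (
        (out["sig_id"] != "")
        & (out["cell_id"] != "")
        & (out["pert_id"] != "")
        & (out["pert_category"] != UNKNOWN_CATEGORY)
        & out["time_h"].notna()
        & out["n_replicates"].notna()
        & (out["n_replicates"] >= 1)
        & ~out["sig_id"].duplicated(keep="first")
    )
    out = out.loc[keep].reset_index(drop=True)
    out["n_replicates"] = out["n_replicates"].astype(int)
    dropped = n_in - len(out)
    if dropped:
        logger.info("read_metadata: dropped %d of %d rows", dropped, n_in)
    return out[list(METADATA_COLUMNS)]


def write_metadata(meta: pd.DataFrame, path) -> None:
    """Write a canonical metadata table as TSV (readable by read_metadata
    under an identity dialect)."""
    dialect = {
        "pert_type": "pert_category",
        "dose": "dose_um",
        "time": "time_h",
    }
    table = meta.copy()
    # round-trip through the real pert_type codes so one reader serves all
    inverse = {
        "compound": "trt_cp",
        "ligand": "trt_lig",
        "shRNA": "trt_sh",
        "overexpression": "trt_oe",
        "control": "ctl_vehicle",
        "poscon": "trt_poscon",
    }
    table["pert_type"] = table["pert_category"].map(inverse)
    table["pert_dose"] = table["dose_um"].fillna(-666)
    table["pert_dose_unit"] = np.where(table["dose_um"].notna(), "uM", MISSING_SENTINEL)
    table["pert_time"] = table["time_h"]
    table["distil_nsample"] = table["n_replicates"]
    cols = [
        "sig_id",
        "cell_id",
        "pert_id",
        "pert_iname",
        "pert_type",
        "pert_dose",
        "pert_dose_unit",
        "pert_time",
        "distil_nsample",
    ]
    table[cols].to_csv(path, sep="\t", index=False)
    del dialect  # documented identity mapping; writer emits sig_info names


# ---------------------------------------------------------------------------
# GCT 1.3 (text) and GCTX (HDF5)

GCT_VERSION = "#1.3"
_GCTX_DATA_NODE = "0/DATA/0/matrix"
_GCTX_ROW_META = "0/META/ROW/id"
_GCTX_COL_META = "0/META/COL/id"


def _sniff_format(path) -> str:
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return "gctx"
    return "gct"


def read_zscore_matrix(path) -> SignatureMatrix:
    """Read a GCT 1.3 text file or GCTX HDF5 file into a SignatureMatrix.

    The format is detected from the file content (HDF5 magic bytes), not
    the extension.  Values are taken as-is, without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _sniff_format(path) == "gctx":
        return _read_gctx(path)
    return _read_gct(path)


def _read_gct(path: Path) -> SignatureMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        version = fh.readline().rstrip("\n")
        if version != GCT_VERSION:
            raise ValueError(
                f"{path}: unsupported GCT version line {version!r}; expected {GCT_VERSION!r}"
            )
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) not in (2, 4):
            raise ValueError(f"{path}, line 2: malformed dimension line {dims!r}")
        try:
            nums = [int(d) for d in dims]
        except ValueError as exc:
            raise ValueError(f"{path}, line 2: non-integer dimensions {dims!r}") from exc
        n_rows, n_cols = nums[0], nums[1]
        n_rmeta = nums[2] if len(nums) == 4 else 0
        n_cmeta = nums[3] if len(nums) == 4 else 0

        header = fh.readline().rstrip("\n").split("\t")
        expected_width = 1 + n_rmeta + n_cols
        if len(header) != expected_width:
            raise ValueError(
                f"{path}, line 3: expected {expected_width} header fields "
                f"(1 id + {n_rmeta} row-metadata + {n_cols} columns), found {len(header)}"
            )
        sig_ids = header[1 + n_rmeta :]

        for i in range(n_cmeta):  # column metadata rows are skipped
            fh.readline()

        gene_ids: list[str] = []
        rows = np.empty((n_rows, n_cols), dtype=float)
        for i in range(n_rows):
            line = fh.readline()
            if not line:
                raise ValueError(
                    f"{path}: body ended after {i} data rows; expected {n_rows}"
                )
            fields = line.rstrip("\n").split("\t")
            if len(fields) != expected_width:
                raise ValueError(
                    f"{path}, data row {i + 1}: expected {expected_width} fields, "
                    f"found {len(fields)}"
                )
            gene_ids.append(fields[0])
            rows[i] = [_gct_value(v) for v in fields[1 + n_rmeta :]]
        extra = fh.readline()
        if extra.strip():
            raise ValueError(f"{path}: trailing data beyond declared {n_rows} rows")
    return SignatureMatrix(gene_ids=gene_ids, sig_ids=list(sig_ids), z=rows)


def _gct_value(text: str) -> float:
    text = text.strip()
    if text in ("", "NA", "NaN", "nan"):
        return math.nan
    return float(text)


def _read_gctx(path: Path) -> SignatureMatrix:
    with h5py.File(path, "r") as fh:
        for node in (_GCTX_DATA_NODE, _GCTX_ROW_META, _GCTX_COL_META):
            if node not in fh:
                raise ValueError(f"{path}: GCTX node {node!r} missing")
        gene_ids = [_decode(x) for x in fh[_GCTX_ROW_META][...]]
        sig_ids = [_decode(x) for x in fh[_GCTX_COL_META][...]]
        data = np.asarray(fh[_GCTX_DATA_NODE][...], dtype=float)
    # stored signature-major (columns x genes), as written by cmap tooling
    if data.shape != (len(sig_ids), len(gene_ids)):
        raise ValueError(
            f"{path}: matrix shape {data.shape} does not match "
            f"{len(sig_ids)} signatures x {len(gene_ids)} genes"
        )
    return SignatureMatrix(gene_ids=gene_ids, sig_ids=sig_ids, z=data.T.copy())


def _decode(x) -> str:
    return x.decode("utf-8") if isinstance(x, bytes) else str(x)


def write_zscore_matrix(matrix: SignatureMatrix, path, format: str = "gct") -> None:
    """Write a SignatureMatrix as GCT 1.3 text or GCTX HDF5.

    Round-trips through :func:`read_zscore_matrix` with identical
    identifiers; values are preserved exactly in GCTX and to float
    representation precision in GCT text.
    """
    fmt = format.lower().lstrip(".")
    if fmt == "gct":
        _write_gct(matrix, path)
    elif fmt == "gctx":
        _write_gctx(matrix, path)
    else:
        raise ValueError(f"unsupported format {format!r}; use 'gct' or 'gctx'")


def _write_gct(matrix: SignatureMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(GCT_VERSION + "\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_signatures}\t0\t0\n")
        fh.write("\t".join(["id", *matrix.sig_ids]) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.z):
            fields = [gene] + [repr(float(v)) if not math.isnan(v) else "NA" for v in row]
            fh.write("\t".join(fields) + "\n")


def _write_gctx(matrix: SignatureMatrix, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset(_GCTX_DATA_NODE, data=np.ascontiguousarray(matrix.z.T))
        fh.create_dataset(
            _GCTX_ROW_META, data=np.array([g.encode() for g in matrix.gene_ids])
        )
        fh.create_dataset(
            _GCTX_COL_META, data=np.array([s.encode() for s in matrix.sig_ids])
        )
        fh.attrs["version"] = "GCTX1.0"
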