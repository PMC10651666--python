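"""Readers and writers for the package's plain-text formats.

Counts travel as TSV (genes x samples, first column ``gene``) or as a
MatrixMarket triplet (``.mtx`` plus ``.rows``/``.cols`` sidecars);
sample metadata, truth tables, DE tables, probe/gene statistics tables
and gene lists are TSV / one-symbol-per-line text.  Every writer's
output is re-parseable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml

from .diffexpr import DEResult
from .errors import ParseError
from .simulate import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_meta",
    "write_sample_meta",
    "read_de_result",
    "write_de_result",
    "read_gene_list",
    "write_gene_list",
    "read_probe_table",
    "write_table",
    "read_yaml",
    "write_json",
    "write_section_image",
    "read_section_image",
]


def _coerce_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{source}: duplicate gene identifier {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise ParseError(f"{source}: non-numeric values in column {bad!r}")
    if np.isnan(arr).any():
        g = df.index[np.isnan(arr).any(axis=1)][0]
        raise ParseError(f"{source}: missing value at gene {g!r}")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{source}: negative count at gene {df.index[i]!r} (row {i + 2}), "
            f"sample {df.columns[j]!r}"
        )
    if not np.allclose(arr, np.rint(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.rint(arr)))[0]
        raise ParseError(
            f"{source}: non-integer count at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df.astype(np.int64)


def read_counts(path: str | Path, meta_path: str | Path | None = None) -> CountMatrix | pd.DataFrame:
    """Load a count matrix from TSV or MatrixMarket.

    For ``.mtx`` input, ``<stem>.rows`` and ``<stem>.cols`` sidecars
    supply gene and sample identifiers.  With ``meta_path`` the result
    is a validated :class:`CountMatrix`; otherwise the bare DataFrame.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        genes = path.with_suffix(".rows").read_text().split()
        samples = path.with_suffix(".cols").read_text().split()
        df = pd.DataFrame(np.asarray(mat.todense() if sp.issparse(mat) else mat),
                          index=pd.Index(genes, name="gene"), columns=samples)
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed header/body
            raise ParseError(f"{path}: {exc}") from exc
        df.index.name = "gene"
    df = _coerce_counts(df, str(path))
    if meta_path is None:
        return df
    meta = read_sample_meta(meta_path)
    cm = CountMatrix(counts=df, sample_meta=meta)
    cm.validate()
    return cm


def write_counts(cm: CountMatrix | pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    df = cm.counts if isinstance(cm, CountMatrix) else cm
    path = Path(path)
    if fmt == "tsv":
        df.rename_axis("gene").to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(path.with_suffix(".mtx"), sp.coo_matrix(df.to_numpy()))
        path.with_suffix(".rows").write_text("\n".join(map(str, df.index)) + "\n")
        path.with_suffix(".cols").write_text("\n".join(map(str, df.columns)) + "\n")
    else:
        raise ParseError(f"unknown counts format {fmt!r}")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("sex", "age_group"):
        if col not in meta.columns:
            raise ParseError(f"{path}: metadata must have a {col!r} column")
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t")


def read_de_result(path: str | Path, sex: str) -> DEResult:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    need = {"log2fc", "p_value", "neg_log10_p"}
    if not need <= set(tab.columns):
        raise ParseError(f"{path}: DE table must have columns {sorted(need)}")
    return DEResult(table=tab, sex=sex)


def write_de_result(de: DEResult, path: str | Path) -> None:
    de.table.rename_axis("gene").to_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln and not ln.startswith("#")]
    if not genes:
        raise ParseError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_probe_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    need = {"gene", "probe", "log2fc", "p_value"}
    if not need <= set(tab.columns):
        raise ParseError(f"{path}: probe table must have columns {sorted(need)}")
    return tab


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_section_image(image: np.ndarray, path: str | Path) -> None:
    """Save a two-channel section image.

    ``.png`` writes an 8-bit RGB file with the green (MYH7) channel in
    G and the red (dystrophin) channel in R; ``.tif``/``.tiff`` writes a
    16-bit two-plane TIFF (8-bit values scaled by 257).
    """
    path = Path(path)
    if image.ndim != 3 or image.shape[2] < 2:
        raise ParseError("expected an (H, W, 2) image")
    if path.suffix == ".png":
        from PIL import Image

        rgb = np.zeros((*image.shape[:2], 3), dtype=np.uint8)
        rgb[..., 1] = image[..., 0]
        rgb[..., 0] = image[..., 1]
        Image.fromarray(rgb).save(path)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, (image[..., :2].astype(np.uint16) * 257))
    else:
        raise ParseError(f"unsupported image format {path.suffix!r}")


def read_section_image(path: str | Path) -> np.ndarray:
    """Load a section image back into (H, W, 2) uint8, channels (green, red)."""
    path = Path(path)
    if path.suffix == ".png":
        from PIL import Image

        rgb = np.asarray(Image.open(path).convert("RGB"))
        return np.stack([rgb[..., 1], rgb[..., 0]], axis=-1)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
        return (arr[..., :2] // 257).astype(np.uint8)
    raise ParseError(f"unsupported image format {path.suffix!r}")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a YAML mapping")
    return data


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, allow_nan=True) + "\n")
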