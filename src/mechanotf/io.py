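"""Readers and writers for the pipeline's external formats.

Tabular inputs are tab- or whitespace-separated text; images are
single-channel TIFF or PNG. Raw STRING protein-link files (space-separated
with a ``combined_score`` column and ``9606.``-style species prefixes) are
accepted alongside the minimal three-column edge table. Every filtering
step (self-loops, duplicate pairs) logs a count, because downstream set
sizes are filter outcomes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mechanotf")

_SPECIES_PREFIX = re.compile(r"^\d+\.")


@dataclass(frozen=True)
class InteractionRecord:
    """Undirected protein-protein interaction with a STRING-style
    integer confidence score in [0, 1000]."""

    gene_a: str
    gene_b: str
    score: int


@dataclass(frozen=True)
class TFTargetRecord:
    """Directed transcription-factor -> target-gene annotation."""

    tf: str
    target: str


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration for a pipeline run.

    ``log_base`` selects the base of the edge-cost transform (10 or "e");
    ``beta`` scales node prizes in the PCST objective; percentiles use
    linear interpolation between order statistics throughout.
    """

    log_base: str = "10"             # "10" or "e"
    beta: float = 1.0
    num_components: int = 1
    seed: int = 0
    padj_threshold: float = 0.05
    percentile_convention: str = "linear"
    shell_width: int = 3
    min_nucleus_area: int = 100
    min_focus_area: int = 5
    alpha: float = 0.05
    out_dir: str = "results"

    def validate(self) -> None:
        if self.log_base not in ("10", "e"):
            raise ValueError(f"log_base must be '10' or 'e', got {self.log_base!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.num_components < 1:
            raise ValueError("num_components must be >= 1")
        if not 0 < self.padj_threshold <= 1:
            raise ValueError("padj_threshold must be in (0, 1]")
        if self.shell_width < 1:
            raise ValueError("shell_width must be >= 1")
        if self.percentile_convention != "linear":
            raise ValueError("only the 'linear' percentile convention is supported")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**{k: raw[k] for k in raw})
    cfg.log_base = str(cfg.log_base)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    cfg.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, default_flow_style=False, sort_keys=True)


def _strip_prefix(symbol: str) -> str:
    return _SPECIES_PREFIX.sub("", symbol)


def read_edge_table(path: str | Path) -> list[InteractionRecord]:
    """Read a PPI edge table: three columns (gene_a, gene_b, score).

    Accepts a minimal TSV or a raw STRING protein-links file (header
    ``protein1 protein2 combined_score``, species prefixes stripped).
    Self-loops are dropped and counted; duplicate undirected pairs keep
    the maximum score.

    Raises
    ------
    ValueError
        On a malformed row (with its line number) or a score outside
        [0, 1000].
    """
    records: dict[tuple[str, str], int] = {}
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_score = parts
            if lineno == 1 and not _is_int(raw_score):
                # header row (STRING files carry "combined_score")
                continue
            if not _is_int(raw_score):
                raise ValueError(f"{path}:{lineno}: score {raw_score!r} is not an integer")
            score = int(raw_score)
            if not 0 <= score <= 1000:
                raise ValueError(f"{path}:{lineno}: score out of range [0, 1000]: {score}")
            a, b = _strip_prefix(a), _strip_prefix(b)
            if a == b:
                n_self_loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in records:
                records[key] = max(records[key], score)
            else:
                records[key] = score
    if n_self_loops:
        logger.info("read_edge_table: dropped %d self-loop(s)", n_self_loops)
    return [InteractionRecord(a, b, s) for (a, b), s in sorted(records.items())]


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def write_edge_table(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene_a}\t{r.gene_b}\t{r.score}\n")


def read_tf_target_table(path: str | Path) -> list[TFTargetRecord]:
    """Read a directed TF -> target edge table (two columns); duplicates
    are collapsed."""
    seen: set[tuple[str, str]] = set()
    out: list[TFTargetRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            if lineno == 1 and parts[0].lower() in ("tf", "regulator", "source"):
                continue
            pair = (_strip_prefix(parts[0]), _strip_prefix(parts[1]))
            if pair not in seen:
                seen.add(pair)
                out.append(TFTargetRecord(*pair))
    return out


def write_tf_target_table(records: Iterable[TFTargetRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.tf}\t{r.target}\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table with header columns
    ``gene``, ``log2fc``, ``padj`` (one row per gene).

    Raises
    ------
    ValueError
        On a missing column, a duplicated gene, a non-finite log2fc, or
        an adjusted p outside [0, 1].
    """
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("gene", "log2fc", "padj"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df[["gene", "log2fc", "padj"]].copy()
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicated gene(s): {sorted(df.loc[dup, 'gene'])}")
    if not np.isfinite(df["log2fc"]).all():
        raise ValueError(f"{path}: non-finite log2fc value(s)")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any() or df["padj"].isna().any():
        raise ValueError(f"{path}: padj outside [0, 1]")
    return df.reset_index(drop=True)


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene", "log2fc", "padj"]].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list (one symbol per line, blank lines
    ignored) into a de-duplicated, order-preserving list."""
    seen: set[str] = set()
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if not sym:
                continue
            if sym not in seen:
                seen.add(sym)
                out.append(sym)
    if not out:
        raise ValueError(f"{path}: empty gene list")
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# images


def read_image(path: str | Path, channel: int | None = None,
               z_policy: str | None = None) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF/PNG into a non-negative 2-D float array.

    Multi-channel images require ``channel``; z-stacks require
    ``z_policy`` ("max" or "mean"). The original bit depth is kept in the
    returned metadata dict only — all metrics downstream are either
    ratios or areas, so the intensity scale is immaterial.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    meta = {"dtype": str(arr.dtype), "path": str(path)}
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):  # channel-last RGB(A)
            if channel is None:
                raise ValueError(f"{path}: multi-channel image requires a channel index")
            arr = arr[..., channel]
        else:  # z-stack
            if z_policy is None:
                raise ValueError(f"{path}: 3-D stack requires z_policy ('max' or 'mean')")
            if z_policy == "max":
                arr = arr.max(axis=0)
            elif z_policy == "mean":
                arr = arr.mean(axis=0)
            else:
                raise ValueError(f"unknown z_policy {z_policy!r}")
    elif arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    out = np.asarray(arr, dtype=float)
    out = np.clip(out, 0, None)
    return out, meta


def write_image(arr: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# packaged supplementary stand-ins


def load_table_s2_genes() -> list[str]:
    """Load the packaged 119-gene differentially-expressed list.

    The shipped file is a synthetic stand-in at the real list's size: it
    contains the six TFs reported to overlap the DEG list (NR4A1, CEBPD,
    KLF9, ZNF331, IRF1, NR6A1) plus clearly synthetic placeholder symbols,
    because the original supplementary table is not redistributable here.
    """
    ref = resources.files("mechanotf.data") / "table_s2_genes.synthetic.txt"
    with resources.as_file(ref) as p:
        return read_gene_list(p)


def load_inhibitor_table() -> pd.DataFrame:
    """Load the packaged 15-row inhibitor screen table.

    The ``target`` column carries the screen's real 15 targets; inhibitor
    names and concentrations are synthetic placeholders except where the
    text names them (Stattic for STAT3), hence the ``synthetic`` filename.
    """
    ref = resources.files("mechanotf.data") / "table1_inhibitors.synthetic.tsv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
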