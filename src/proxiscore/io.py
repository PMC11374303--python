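"""Readers and writers for the pipeline's tab-separated interchange formats.

All tabular outputs carry a leading ``#`` comment header with the package
version and a hash of the run configuration, so an output file identifies
the run that produced it; readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "config_hash",
    "read_quant_table", "write_quant_table",
    "read_design", "write_design",
    "read_id_list", "write_id_list",
    "read_contrast", "write_contrast",
    "read_sec_run", "write_sec_run",
    "read_sites", "write_sites",
    "load_config", "dump_config",
]


def config_hash(config: dict | None) -> str:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: dict | None) -> str:
    return f"# proxiscore {__version__} config={config_hash(config)}\n"


def _write_tsv(df: pd.DataFrame, path, config: dict | None,
               index_label: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index_label=index_label)


def _read_tsv(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_quant_table(table: pd.DataFrame, path, config: dict | None = None) -> None:
    _write_tsv(table, path, config, "protein_id")


def read_quant_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_design(design: pd.DataFrame, path, config: dict | None = None) -> None:
    _write_tsv(design, path, config, "sample_id")


def read_design(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_id_list(ids, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_id_list(path) -> set[str]:
    lines = Path(path).read_text().splitlines()
    return {ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")}


def write_contrast(result, path, config: dict | None = None) -> None:
    cols = ["mean_log2_ratio", "p_value", "q_value", "n_pairs"]
    _write_tsv(result.table[cols], path, config, "protein_id")


def read_contrast(path):
    from .diffabund import ContrastResult
    tab = _read_tsv(path)
    tab["degenerate"] = False
    return ContrastResult(tab)


def write_sec_run(run: pd.DataFrame, path, config: dict | None = None) -> None:
    _write_tsv(run, path, config, "protein_id")


def read_sec_run(path) -> pd.DataFrame:
    run = _read_tsv(path)
    run.columns = [int(c) for c in run.columns]
    return run


def write_sites(sites: pd.DataFrame, path, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config))
        sites.to_csv(fh, sep="\t", index=False)


def read_sites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(config: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
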