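"""Readers and writers for the plain-text formats the pipeline exchanges.

Tables are tab-separated with a header row; gene sets use the GMT
convention (set name, description, then tab-separated members, one set
per line); gene lists are one identifier per line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ValidationError


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path):
    """Read a GMT file into a list of :class:`~coopsyn.enrichment.GeneSet`."""
    from .enrichment import GeneSet

    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            sets.append(GeneSet(set_id=fields[0], name=fields[1], members=tuple(fields[2:])))
    return sets


def write_gmt(sets: Iterable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *gs.members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".json"}:
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return data
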