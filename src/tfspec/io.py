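"""Configuration files, run manifests, and tabular output writers.

Canonical tabular format: TSV (tab-separated, '.' decimal, UTF-8) with
'#'-prefixed metadata lines before the header row, plus a JSON manifest
sidecar carrying the fully resolved parameter set, the root seed and the
package version.  Identical config + seed reproduce byte-identical TSVs
(timestamps live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams

__all__ = [
    "load_config",
    "save_config",
    "RunManifest",
    "write_tsv",
    "read_tsv",
    "state_table",
    "write_fasta_genotype",
]


def load_config(path: str | Path, **overrides) -> ModelParams:
    """Read a YAML or JSON config into :class:`ModelParams`.

    Unknown keys raise; ``overrides`` (e.g. from CLI flags) take precedence.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(ModelParams)} | {"Ns"}
    bad = set(data) - valid
    if bad:
        raise ValueError(f"unknown config fields: {sorted(bad)}")
    return ModelParams.from_dict(data)


def save_config(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record written next to every output file."""

    command: str
    params: dict
    seed: int | None = None
    version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S", time.gmtime()))
    extra: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True, default=str) + "\n")


def write_tsv(path: str | Path, df: pd.DataFrame, metadata: dict | None = None,
              float_format: str = "%.12g") -> None:
    """Write a DataFrame as TSV with '#'-prefixed metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def state_table(space, labels=None, distributions: dict | None = None) -> pd.DataFrame:
    """One row per reduced genotype: M, k_ij, sigma_i, neutral weight,
    macrostate, plus any named probability columns."""
    n_G = space.k.shape[2]
    cols = {"M": space.M.astype(int)}
    for i in range(2):
        for j in range(n_G):
            cols[f"k_{i + 1}{j + 1}"] = space.k[:, i, j].astype(int)
    for i in range(2):
        cols[f"sigma_{i + 1}"] = [format(s, "02b") for s in space.sigma[:, i]]
    cols["neutral_weight"] = space.weights
    if labels is not None:
        cols["macrostate"] = labels
    for name, P in (distributions or {}).items():
        cols[name] = P
    return pd.DataFrame(cols)


_LETTERS = np.array(list("ACGT"))


def write_fasta_genotype(path: str | Path, cons1, cons2, sites, sigma,
                         name: str = "genotype") -> None:
    """Export one explicit genotype (consensus + site sequences) as FASTA
    with structured headers."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for label, seq, desc in (
        ("TF1_consensus", cons1, f"sigma={format(int(sigma[0]), '02b')}"),
        ("TF2_consensus", cons2, f"sigma={format(int(sigma[1]), '02b')}"),
    ):
        records.append(SeqRecord(Seq("".join(_LETTERS[np.asarray(seq)])),
                                 id=f"{name}|{label}", description=desc))
    for j, site in enumerate(np.atleast_2d(sites)):
        records.append(SeqRecord(Seq("".join(_LETTERS[np.asarray(site)])),
                                 id=f"{name}|site_gene{j + 1}", description=""))
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")
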