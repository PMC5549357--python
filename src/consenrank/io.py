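"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is TSV/GMT/JSON so artifacts stay diffable and the pipeline
manifest can checksum them.  Readers hand back the same in-memory objects
the stage functions consume, and a written-then-reread artifact
round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .consensus import ConsensusTable, RankedGeneList

__all__ = [
    "write_ranked_lists",
    "read_ranked_lists",
    "write_string_edges",
    "read_string_edges",
    "write_gmt",
    "read_gmt",
    "write_study_tables",
    "read_study_tables",
    "write_consensus_table",
    "read_consensus_table",
    "write_truth",
    "read_truth",
]


def write_ranked_lists(lists: list[RankedGeneList], path) -> None:
    frames = [
        pd.DataFrame({"method": rl.method_id, "gene_id": rl.gene_ids, "score": rl.scores})
        for rl in lists
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_ranked_lists(path) -> list[RankedGeneList]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    out = []
    for method, grp in df.groupby("method", sort=True):
        out.append(
            RankedGeneList(
                method_id=str(method),
                gene_ids=list(grp["gene_id"]),
                scores=grp["score"].to_numpy(),
            )
        )
    return out


def write_string_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_string_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})


def write_gmt(collection: dict[str, set], path, descriptions: dict[str, str] | None = None) -> None:
    """Gene-set collection in GMT: name <tab> description <tab> members..."""
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path) -> dict[str, set]:
    collection: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = fields[0]
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            collection[name] = set(fields[2:])
    return collection


def write_study_tables(studies: dict[str, pd.DataFrame], path) -> None:
    frames = []
    for study in sorted(studies):
        df = studies[study].copy()
        df.insert(0, "study", study)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_study_tables(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return {
        str(study): grp.drop(columns="study").reset_index(drop=True)
        for study, grp in df.groupby("study", sort=True)
    }


def write_consensus_table(table: ConsensusTable, path) -> None:
    out = table.df.reset_index().rename(columns={"index": "gene_id"})
    out.to_csv(path, sep="\t", index=False)


def read_consensus_table(path, n_methods: int) -> ConsensusTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    return ConsensusTable(df=df, n_methods=n_methods)


def write_truth(truth: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True, default=_default))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
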