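"""Plain-text readers/writers: FASTA (via Biopython), tab-delimited tables.

Protein metadata rides in the FASTA description as ``key=value`` tokens
(source, genus, annotations comma-joined), so databases round-trip without a
sidecar file.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .psm import PSM_COLUMNS
from .seqdb import OrthologCluster, ProteinRecord


def write_fasta(path, proteins) -> None:
    records = []
    for p in proteins:
        desc = [f"source={p.source}"]
        if p.genus:
            desc.append(f"genus={p.genus}")
        if p.annotations:
            desc.append("annotations=" + ",".join(sorted(p.annotations)))
        records.append(
            SeqRecord(Seq(p.sequence), id=p.id, description=" ".join(desc))
        )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                fields[k] = v
        out.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq),
                source=fields.get("source", "reference"),
                genus=fields.get("genus"),
                annotations=frozenset(
                    a for a in fields.get("annotations", "").split(",") if a
                ),
            )
        )
    return out


def write_psms(path, psms: pd.DataFrame) -> None:
    psms.to_csv(path, sep="\t", index=False, columns=PSM_COLUMNS)


def read_psms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "run_id": str,
                                            "sample_id": str})
    df["is_decoy"] = df["is_decoy"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes")
    )
    return df[PSM_COLUMNS]


def write_clusters(path, clusters) -> None:
    rows = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        for m in sorted(c.members):
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "member_id": m,
                    "representative_flag": int(m == c.representative),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> list:
    df = pd.read_csv(path, sep="\t")
    clusters = []
    for cid, grp in df.groupby("cluster_id"):
        reps = grp.loc[grp["representative_flag"] == 1, "member_id"]
        clusters.append(
            OrthologCluster(
                cluster_id=str(cid),
                members=frozenset(grp["member_id"].astype(str)),
                representative=str(reps.iloc[0]) if len(reps) else
                str(sorted(grp["member_id"].astype(str))[0]),
            )
        )
    return sorted(clusters, key=lambda c: c.cluster_id)


def write_matrix(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_module_definitions(path, module_definitions: dict) -> None:
    rows = [
        {"module_id": mid, "ko_id": ko}
        for mid in sorted(module_definitions)
        for ko in sorted(module_definitions[mid])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_module_definitions(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        str(mid): set(grp["ko_id"].astype(str))
        for mid, grp in df.groupby("module_id")
    }


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
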