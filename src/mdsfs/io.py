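"""Standard-format I/O: labeled FASTA input, run outputs, trace serialization.

Sequences arrive as FASTA; labels either as a side-car TSV
(``seq_id<TAB>label``) or extracted from FASTA headers with a regex.  A
finished run writes four files into the output directory: the full ranking
(TSV), the search trace (JSON), a selection summary (JSON) and an echo of
the effective configuration (YAML).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from Bio import SeqIO

from .errors import MDSFSError
from .search import RankingResult, SearchTrace, LevelRecord
from .attributes import AttributeTable, load_default_table


def read_labeled_fasta(
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    label_from_header: str | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Read sequences and class labels.

    Exactly one of ``labels_path`` (side-car TSV ``seq_id<TAB>label``) or
    ``label_from_header`` (regex whose first group captures the label from
    the FASTA description) must be given.  Residues are case-folded to
    uppercase; record order is preserved; ids must be unique and every id
    must receive a label.

    Returns
    -------
    (sequences, labels, seq_ids)
    """
    if (labels_path is None) == (label_from_header is None):
        raise MDSFSError(
            "provide exactly one of a labels TSV or a header-label regex"
        )
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise MDSFSError(f"no FASTA records in {fasta_path}")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise MDSFSError(f"duplicate sequence id(s): {sorted(dupes)}")
    sequences = [str(r.seq).upper() for r in records]

    if labels_path is not None:
        mapping: dict[str, str] = {}
        with open(labels_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise MDSFSError(
                        f"{labels_path}:{lineno}: expected 'seq_id<TAB>label'"
                    )
                mapping[parts[0]] = parts[1]
        missing = [i for i in ids if i not in mapping]
        if missing:
            raise MDSFSError(f"label TSV is missing id(s): {missing}")
        labels = [mapping[i] for i in ids]
    else:
        pattern = re.compile(label_from_header)
        labels = []
        for rec in records:
            m = pattern.search(rec.description)
            if not m:
                raise MDSFSError(
                    f"header of {rec.id!r} does not match label regex"
                )
            labels.append(m.group(1))
    return sequences, labels, ids


def write_fasta(
    sequences: Sequence[str], seq_ids: Sequence[str], path: str | Path,
    width: int = 60,
) -> None:
    """Write plain multi-line FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for sid, seq in zip(seq_ids, sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_labels(
    labels: Sequence, seq_ids: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for sid, lab in zip(seq_ids, labels):
            fh.write(f"{sid}\t{lab}\n")


def trace_to_dict(trace: SearchTrace) -> dict:
    return {
        "scheme": trace.scheme,
        "levels": [
            {
                "level": rec.level,
                "alpha": rec.alpha,
                "n_candidates": rec.n_candidates,
                "candidates": [
                    {"subset": "".join(sub), "alpha": a}
                    for sub, a in rec.candidates
                ],
                "beam": ["".join(sub) for sub in rec.beam],
            }
            for rec in trace.levels
        ],
    }


def trace_from_dict(payload: Mapping) -> SearchTrace:
    levels = tuple(
        LevelRecord(
            level=rec["level"],
            alpha=rec["alpha"],
            candidates=tuple(
                (tuple(c["subset"]), c["alpha"]) for c in rec["candidates"]
            ),
            beam=tuple(tuple(b) for b in rec["beam"]),
        )
        for rec in payload["levels"]
    )
    return SearchTrace(scheme=payload["scheme"], levels=levels)


def write_outputs(
    result: RankingResult,
    selected: Sequence[str],
    config: Mapping,
    outdir: str | Path,
    table: AttributeTable | None = None,
) -> dict[str, Path]:
    """Persist a completed run: ranking TSV, trace JSON, summary JSON, config YAML."""
    if table is None:
        table = load_default_table()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranking": outdir / "ranking.tsv",
        "trace": outdir / "trace.json",
        "selection": outdir / "selection.json",
        "config": outdir / "config.yaml",
    }

    with open(paths["ranking"], "w") as fh:
        fh.write("rank\tsymbol\tname\n")
        for rank, sym in enumerate(result.ranking, 1):
            fh.write(f"{rank}\t{sym}\t{table[sym].name}\n")

    with open(paths["trace"], "w") as fh:
        json.dump(trace_to_dict(result.trace), fh, indent=1)
        fh.write("\n")

    selected = list(selected)
    alphas = result.trace.alphas
    summary = {
        "scheme": result.scheme,
        "criterion": str(config.get("criterion", "")),
        "selected_subset": "".join(selected),
        "selected_size": len(selected),
        "alpha": max(alphas),
        "alpha_per_level": list(alphas),
        "n_evaluations": result.evaluations,
    }
    with open(paths["selection"], "w") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
    return paths


def write_trace_summary_tsv(result: RankingResult, path: str | Path) -> None:
    """Per-level one-line summary: level, best subset, alpha_l, evaluations so far."""
    with open(path, "w") as fh:
        fh.write("level\tbest_subset\talpha_l\tn_candidates\n")
        for rec in result.trace.levels:
            fh.write(
                f"{rec.level}\t{''.join(rec.beam[0])}\t{rec.alpha:.6f}"
                f"\t{rec.n_candidates}\n"
            )
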