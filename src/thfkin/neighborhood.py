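"""Gene-neighborhood classification of folK paralogs.

Many bacterial genomes carry two folK copies; chromosomal context sorts
them into functional groups.  A folK gene is classified by whether a
panB gene, a folB gene, or both lie within a window (default 10) of
coding sequences of it on the same replicon, counting CDS ordinal
distance.  The window is inclusive; strand is ignored; distances across
replicons are infinite.  Circular replicons (opt-in flag) measure
distance the short way around.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "GeneRecord",
    "NeighborhoodCall",
    "parse_annotations",
    "classify_folk",
    "summarize_genomes",
    "calls_to_frame",
]

_TARGETS = ("panb", "folb")


@dataclass(frozen=True)
class GeneRecord:
    genome: str
    replicon: str
    ordinal: int  # 0-based CDS index on the replicon, in coordinate order
    gene: str | None  # lower-cased label, e.g. "folk"; None if unlabeled
    strand: str = "+"


@dataclass
class NeighborhoodCall:
    folk: GeneRecord
    call_class: str  # "panB-clustered" | "folB-clustered" | "both" | "neither"
    dist_panb: int | None  # CDS-count distance to nearest panB (None if absent)
    dist_folb: int | None


def parse_annotations(
    source,
    fmt: str | None = None,
    label_attr: str = "gene",
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Read CDS records from a GFF3 file or a TSV gene table.

    GFF3: one record per CDS feature, ordinals assigned by sorting CDS
    start coordinates within each seqid (so a shuffled file yields the
    same ordinals as a sorted one); gene labels come from ``label_attr``
    (case-insensitive).  TSV: columns genome, replicon, ordinal, gene,
    strand.
    """
    path = os.fspath(source)
    if fmt is None:
        fmt = "tsv" if path.endswith((".tsv", ".txt", ".tab")) else "gff3"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"ordinal": int})
        needed = {"genome", "replicon", "ordinal", "gene"}
        if not needed.issubset(df.columns):
            raise ValueError(f"gene table needs columns {sorted(needed)}")
        records = [
            GeneRecord(
                genome=str(r.genome),
                replicon=str(r.replicon),
                ordinal=int(r.ordinal),
                gene=None if pd.isna(r.gene) else str(r.gene).lower(),
                strand=str(getattr(r, "strand", "+")),
            )
            for r in df.itertuples()
        ]
    elif fmt == "gff3":
        records = _parse_gff3(path, label_attr, genome_id)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _check_ordinals(records)
    return records


def _parse_gff3(path: str, label_attr: str, genome_id: str | None) -> list[GeneRecord]:
    import gffutils

    genome = genome_id or os.path.splitext(os.path.basename(path))[0]
    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ValueError(f"could not parse GFF3 {path!r}: {exc}") from exc

    cds = sorted(db.features_of_type("CDS"), key=lambda f: (f.seqid, f.start, f.end))
    records: list[GeneRecord] = []
    counters: dict[str, int] = {}
    for f in cds:
        label = None
        for key in (label_attr, label_attr.capitalize(), label_attr.upper()):
            if key in f.attributes:
                label = f.attributes[key][0].lower()
                break
        ordinal = counters.get(f.seqid, 0)
        counters[f.seqid] = ordinal + 1
        records.append(
            GeneRecord(
                genome=genome, replicon=f.seqid, ordinal=ordinal,
                gene=label, strand=f.strand or "+",
            )
        )
    return records


def _check_ordinals(records: Iterable[GeneRecord]) -> None:
    by_replicon: dict[tuple[str, str], list[int]] = {}
    for r in records:
        by_replicon.setdefault((r.genome, r.replicon), []).append(r.ordinal)
    for key, ords in by_replicon.items():
        if sorted(ords) != list(range(len(ords))):
            raise ValueError(
                f"ordinals on {key} must be unique and contiguous from 0, got {sorted(ords)}"
            )


def _distance(a: int, b: int, n: int, circular: bool) -> int:
    d = abs(a - b)
    return min(d, n - d) if circular else d


def classify_folk(
    genes: list[GeneRecord],
    window: int = 10,
    circular: set[str] | bool = False,
) -> list[NeighborhoodCall]:
    """Classify every folK gene by proximity to panB / folB.

    ``window`` is inclusive (distance <= window clusters).  ``circular``
    may be True (all replicons circular) or a set of replicon ids.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    by_replicon: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_replicon.setdefault((g.genome, g.replicon), []).append(g)

    calls = []
    for (genome, replicon), members in by_replicon.items():
        n = len(members)
        is_circ = circular is True or (isinstance(circular, set) and replicon in circular)
        targets = {
            t: [g.ordinal for g in members if g.gene == t] for t in _TARGETS
        }
        for g in members:
            if g.gene != "folk":
                continue
            dists = {}
            for t in _TARGETS:
                if targets[t]:
                    dists[t] = min(_distance(g.ordinal, o, n, is_circ) for o in targets[t])
                else:
                    dists[t] = None
            near_panb = dists["panb"] is not None and dists["panb"] <= window
            near_folb = dists["folb"] is not None and dists["folb"] <= window
            if near_panb and near_folb:
                cls = "both"
            elif near_panb:
                cls = "panB-clustered"
            elif near_folb:
                cls = "folB-clustered"
            else:
                cls = "neither"
            calls.append(
                NeighborhoodCall(
                    folk=g, call_class=cls,
                    dist_panb=dists["panb"], dist_folb=dists["folb"],
                )
            )
    return calls


def calls_to_frame(calls: list[NeighborhoodCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome": c.folk.genome,
                "replicon": c.folk.replicon,
                "ordinal": c.folk.ordinal,
                "class": c.call_class,
                "dist_panB": c.dist_panb,
                "dist_folB": c.dist_folb,
            }
            for c in calls
        ]
    )


def summarize_genomes(
    calls: list[NeighborhoodCall], genomes: Iterable[str] | None = None
) -> dict:
    """Per-genome folK copy number / class pattern, plus cohort fractions.

    ``genomes`` optionally supplies the full cohort (genomes without any
    folK then count in denominators); by default the cohort is the set of
    genomes appearing in the calls.  Class-pattern fractions are over
    genomes with at least one folK and sum to 1.
    """
    per_genome: dict[str, list[str]] = {}
    for c in calls:
        per_genome.setdefault(c.folk.genome, []).append(c.call_class)
    cohort = sorted(set(genomes) if genomes is not None else per_genome)
    n = len(cohort)
    if n == 0:
        return {
            "per_genome": pd.DataFrame(columns=["genome", "n_folk", "pattern"]),
            "n_genomes": 0,
            "duplicated_fraction": 0.0,
            "pattern_fractions": {},
        }
    rows = []
    patterns: dict[tuple[str, ...], int] = {}
    n_dup = 0
    n_with_folk = 0
    for g in cohort:
        classes = tuple(sorted(per_genome.get(g, [])))
        rows.append({"genome": g, "n_folk": len(classes), "pattern": "+".join(classes) or "none"})
        if classes:
            n_with_folk += 1
            patterns[classes] = patterns.get(classes, 0) + 1
        if len(classes) >= 2:
            n_dup += 1
    return {
        "per_genome": pd.DataFrame(rows),
        "n_genomes": n,
        "duplicated_fraction": n_dup / n,
        "pattern_fractions": {
            "+".join(k): v / n_with_folk for k, v in sorted(patterns.items())
        }
        if n_with_folk
        else {},
    }
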