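"""End-to-end target identification pipeline.

Query compound -> chemically similar annotated baits (union of the 2D
fingerprint arm and the 3D pharmacophore arm) -> the baits' annotated
protein targets -> affinity scoring of every candidate with the
compound-protein interaction network -> ranked target report with a
per-target confidence label: an interaction validated in more than one
assay is high confidence, otherwise low.

The annotation database is a single TSV of compound-protein interaction
records; the loader enforces the ingest filters (positive Kd, single
protein targets, nonempty sequences) and logs what it drops.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from pydantic import BaseModel

from drift.chemio import MoleculeGraph, ProteinSeq
from drift.fingerprint2d import FastIndex, SimilarityHit, fingerprint, search_2d
from drift.pharmacophore3d import (
    MAX_PHARMACOPHORE_ATOMS,
    Pharmacophore3DKey,
    search_3d,
)

logger = logging.getLogger(__name__)

ANNO_COLUMNS = [
    "compound_id",
    "smiles",
    "target_id",
    "target_sequence",
    "affinity_value",
    "measure_type",
    "assay_id",
]


@dataclass
class InteractionRecord:
    compound_id: str
    smiles: str
    target_id: str
    target_sequence: str
    affinity_value: float  # Kd in nM (or Ki/IC50 per measure_type)
    measure_type: str = "Kd"
    assay_id: str = ""

    def __post_init__(self) -> None:
        if self.measure_type == "Kd" and not self.affinity_value > 0:
            raise ValueError(
                f"record {self.compound_id}->{self.target_id}: Kd must be > 0"
            )
        if not self.target_sequence:
            raise ValueError(
                f"record {self.compound_id}->{self.target_id}: empty target sequence"
            )


@dataclass
class Candidate:
    target_id: str
    target_sequence: str
    records: list[InteractionRecord]
    baits: list[SimilarityHit]
    n_assays: int  # max distinct assays over any single bait-target link


@dataclass
class TargetPrediction:
    target_id: str
    score: float
    supporting_baits: list[tuple[str, float, float | None]]  # (mol_id, tc, ph score)
    n_assays: int
    confidence: str  # "high" | "low"
    affinity: float = 0.0


def write_annotation_db(records: list[InteractionRecord], path: str) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=ANNO_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def load_annotation_db(path: str, target_type_filter: bool = True) -> list[InteractionRecord]:
    """Load and validate an annotation TSV.

    Enforced at ingest: Kd records must have Kd > 0; sequences must be
    nonempty; if a ``target_type`` column is present, only SINGLE PROTEIN
    rows are kept.  Dropped row counts are logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "target_id": str, "assay_id": str})
    missing = [c for c in ANNO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    n0 = len(df)
    if target_type_filter and "target_type" in df.columns:
        df = df[df["target_type"].str.upper() == "SINGLE PROTEIN"]
    df = df[~((df["measure_type"] == "Kd") & ~(df["affinity_value"] > 0))]
    df = df[df["target_sequence"].astype(str).str.len() > 0]
    if len(df) < n0:
        logger.info("annotation ingest: dropped %d of %d rows", n0 - len(df), n0)
    return [
        InteractionRecord(
            compound_id=row.compound_id,
            smiles=row.smiles,
            target_id=row.target_id,
            target_sequence=row.target_sequence,
            affinity_value=float(row.affinity_value),
            measure_type=row.measure_type,
            assay_id=str(row.assay_id),
        )
        for row in df.itertuples()
    ]


def find_baits(
    query: MoleculeGraph,
    fpindex: FastIndex | None,
    phdb: list[tuple[str, Pharmacophore3DKey]] | None = None,
    tc_min: float = 0.85,
    min_overlap: float = 0.5,
    k_conformers: int = 10,
    seed: int = 7,
    max_atoms: int = MAX_PHARMACOPHORE_ATOMS,
) -> tuple[list[SimilarityHit], list[str]]:
    """Union of 2D and 3D similarity hits, deduplicated by mol_id.

    Returns ``(hits, notices)``.  When the query exceeds the pharmacophore
    size cap the 3D arm is skipped with a notice and the search is 2D-only.
    """
    if fpindex is None and not phdb:
        raise ValueError("find_baits needs at least one index (2D or 3D)")
    notices: list[str] = []
    merged: dict[str, SimilarityHit] = {}
    if fpindex is not None:
        qfp = fingerprint(query)
        for hit in search_2d(qfp, fpindex, tc_min=tc_min):
            merged[hit.mol_id] = SimilarityHit(mol_id=hit.mol_id, tc=hit.tc)
    if phdb:
        hits3d = search_3d(
            query, k_conformers, phdb, min_overlap=min_overlap, seed=seed, max_atoms=max_atoms
        )
        if hits3d is None:
            notices.append(
                f"query {query.mol_id} exceeds {max_atoms} atoms: "
                "no pharmacophore search performed (2D-only)"
            )
        else:
            for hit in hits3d:
                if hit.mol_id in merged:
                    merged[hit.mol_id].pharmacophore_score = hit.pharmacophore_score
                else:
                    merged[hit.mol_id] = hit
    hits = sorted(
        merged.values(),
        key=lambda h: (-max(h.tc, h.pharmacophore_score or 0.0), h.mol_id),
    )
    return hits, notices


def retrieve_targets(
    baits: list[SimilarityHit],
    annodb: list[InteractionRecord],
    exclude_self: bool = False,
    query_id: str | None = None,
) -> list[Candidate]:
    """Collect the annotated targets of the bait compounds.

    Grouped by target; per-target ``n_assays`` is the largest number of
    distinct assay ids supporting any single bait-target interaction.  With
    ``exclude_self`` the query compound's own annotation records are
    dropped first (unknown-target evaluation mode).
    """
    bait_ids = {b.mol_id: b for b in baits}
    by_target: dict[str, list[InteractionRecord]] = {}
    for rec in annodb:
        if rec.compound_id not in bait_ids:
            continue
        if exclude_self and query_id is not None and rec.compound_id == query_id:
            continue
        by_target.setdefault(rec.target_id, []).append(rec)
    candidates = []
    for target_id in sorted(by_target):
        recs = by_target[target_id]
        link_assays: dict[str, set[str]] = {}
        for r in recs:
            link_assays.setdefault(r.compound_id, set()).add(r.assay_id)
        candidates.append(
            Candidate(
                target_id=target_id,
                target_sequence=recs[0].target_sequence,
                records=recs,
                baits=[bait_ids[c] for c in sorted({r.compound_id for r in recs})],
                n_assays=max(len(s) for s in link_assays.values()),
            )
        )
    return candidates


def rank_targets(
    query: MoleculeGraph,
    candidates: list[Candidate],
    model,
) -> list[TargetPrediction]:
    """Score every candidate with the interaction model and rank.

    ``model`` is any scorer exposing ``predict(mol, ProteinSeq) ->``
    an object with ``affinity`` and ``score``.  Candidates whose sequence
    fails to encode are skipped with a warning, never silently.
    """
    preds: list[TargetPrediction] = []
    for cand in candidates:
        try:
            p = model.predict(query, ProteinSeq(prot_id=cand.target_id, sequence=cand.target_sequence))
        except Exception as exc:  # noqa: BLE001 - report and move on
            logger.warning("skipping target %s: %s", cand.target_id, exc)
            continue
        preds.append(
            TargetPrediction(
                target_id=cand.target_id,
                score=float(p.score),
                supporting_baits=[
                    (b.mol_id, b.tc, b.pharmacophore_score) for b in cand.baits
                ],
                n_assays=cand.n_assays,
                confidence="high" if cand.n_assays > 1 else "low",
                affinity=float(p.affinity),
            )
        )
    preds.sort(key=lambda t: (-t.score, t.target_id))
    return preds


# ----------------------------------------------------------- report schema


class BaitEntry(BaseModel):
    mol_id: str
    tc: float
    pharmacophore_score: float | None = None


class TargetEntry(BaseModel):
    target_id: str
    score: float
    affinity: float
    confidence: str
    n_assays: int
    n_baits: int
    best_tc: float
    supporting_baits: list[str]


class FragmentEntry(BaseModel):
    fragment_key: str
    count: int
    rank: int


class PipelineReport(BaseModel):
    query_id: str
    config: dict
    compounds: list[BaitEntry]
    targets: list[TargetEntry]
    fragments: list[FragmentEntry]
    notices: list[str]


@dataclass
class PipelineConfig:
    fpindex: FastIndex | str | None = None
    phdb: list | str | None = None
    annodb: list[InteractionRecord] | str | None = None
    model: object | str | None = None
    tc_min: float = 0.85
    min_overlap: float = 0.5
    k_conformers: int = 10
    seed: int = 7
    exclude_self: bool = False
    max_atoms: int = MAX_PHARMACOPHORE_ATOMS
    out_json: str | None = None
    out_tsv: str | None = None
    extra: dict = field(default_factory=dict)


def _resolve(config: PipelineConfig):
    from drift.cpinet.model import CPIModel
    from drift.pharmacophore3d import load_pharmacophore_db

    fpindex = config.fpindex
    if isinstance(fpindex, str):
        fpindex = FastIndex.load(fpindex)
    phdb = config.phdb
    if isinstance(phdb, str):
        phdb = load_pharmacophore_db(phdb)
    annodb = config.annodb
    if isinstance(annodb, str):
        annodb = load_annotation_db(annodb)
    if annodb is None:
        raise FileNotFoundError("pipeline config names no annotation database")
    model = config.model
    if isinstance(model, str):
        model = CPIModel.load(model)
    if model is None:
        raise FileNotFoundError("pipeline config names no interaction model")
    return fpindex, phdb, annodb, model


def run_pipeline(query: MoleculeGraph, config: PipelineConfig) -> PipelineReport:
    """Run query -> baits -> targets -> fragments and assemble the report.

    The report validates against the published JSON schema
    (``docs/report.schema.json``); reruns with the same config and seed are
    byte-identical.
    """
    from drift.fragmenter import fragment_frequencies

    fpindex, phdb, annodb, model = _resolve(config)
    hits, notices = find_baits(
        query,
        fpindex,
        phdb,
        tc_min=config.tc_min,
        min_overlap=config.min_overlap,
        k_conformers=config.k_conformers,
        seed=config.seed,
        max_atoms=config.max_atoms,
    )
    candidates = retrieve_targets(
        hits, annodb, exclude_self=config.exclude_self, query_id=query.mol_id
    )
    predictions = rank_targets(query, candidates, model)
    if not predictions:
        notices.append("empty target set: no bait compound has annotated targets")

    by_id = {rec.compound_id: rec for rec in annodb}
    frag_pool = [query]
    for h in hits:
        rec = by_id.get(h.mol_id)
        if rec is not None:
            from drift.chemio import read_molecule

            frag_pool.append(read_molecule(rec.smiles, fmt="smiles", mol_id=rec.compound_id))
    profiles = fragment_frequencies(frag_pool)

    report = PipelineReport(
        query_id=query.mol_id,
        config={
            "tc_min": config.tc_min,
            "min_overlap": config.min_overlap,
            "k_conformers": config.k_conformers,
            "seed": config.seed,
            "exclude_self": config.exclude_self,
        },
        compounds=[
            BaitEntry(mol_id=h.mol_id, tc=h.tc, pharmacophore_score=h.pharmacophore_score)
            for h in hits
        ],
        targets=[
            TargetEntry(
                target_id=t.target_id,
                score=round(t.score, 6),
                affinity=round(t.affinity, 6),
                confidence=t.confidence,
                n_assays=t.n_assays,
                n_baits=len(t.supporting_baits),
                best_tc=max((tc for _, tc, _ in t.supporting_baits), default=0.0),
                supporting_baits=[m for m, _, _ in t.supporting_baits],
            )
            for t in predictions
        ],
        fragments=[
            FragmentEntry(fragment_key=p.fragment_key, count=p.count, rank=p.rank)
            for p in profiles
        ],
        notices=notices,
    )
    if config.out_json:
        with open(config.out_json, "w") as fh:
            fh.write(report.model_dump_json(indent=1))
    if config.out_tsv:
        pd.DataFrame(
            [
                {
                    "target_id": t.target_id,
                    "score": t.score,
                    "confidence": t.confidence,
                    "n_baits": t.n_baits,
                    "best_tc": t.best_tc,
                }
                for t in report.targets
            ]
        ).to_csv(config.out_tsv, sep="\t", index=False)
    return report


def report_json_schema() -> dict:
    """The JSON schema the pipeline report validates against."""
    return PipelineReport.model_json_schema()


def validate_report(data: dict | str) -> PipelineReport:
    """Validate a report dict or JSON string against the schema."""
    if isinstance(data, str):
        return PipelineReport.model_validate_json(data)
    return PipelineReport.model_validate(data)
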