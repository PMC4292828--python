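"""File formats and the end-to-end pipeline.

All delimited files are UTF-8 CSV with a header row (RFC-4180 quoting
via pandas); nested structures (design, reports, manifest) are JSON, or
YAML for design files with a .yaml/.yml suffix. Every writer has a
reader that round-trips exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .allocation import (
    Allocation,
    AllocationConfig,
    ParticipantRecord,
    allocate_sequential,
    impute,
    split_batches,
)
from .design import (
    LinguisticScale,
    QuestionnaireSpec,
    TrialDesign,
    TriangularMembership,
    create_trial,
    default_scale,
    prune_relationship,
)
from .engine import EngineConfig, ExpectedChange, WeightMatrix, expected_changes
from .errors import ParseError, ValidationError
from .evaluation import compare_methods, overlap
from .fuzzy import RelationshipAnswer, build_weight_matrix

log = logging.getLogger("fcmalloc")

DESIGN_SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# Trial design files
# --------------------------------------------------------------------------

def _scale_to_dict(scale: LinguisticScale) -> dict:
    terms = {}
    for t in scale.terms:
        mu = scale.membership[t]
        if not isinstance(mu, TriangularMembership):
            raise ValidationError(
                "only triangular memberships are file-serializable"
            )
        terms[t] = [mu.left, mu.peak, mu.right]
    return {"terms": terms, "order": list(scale.terms),
            "unsure_token": scale.unsure_token}


def _scale_from_dict(d: dict) -> LinguisticScale:
    order = d["order"]
    membership = {t: TriangularMembership(*d["terms"][t]) for t in order}
    return LinguisticScale(terms=tuple(order), membership=membership,
                           unsure_token=d.get("unsure_token", "Unsure"))


def write_design(design: TrialDesign, path: str | Path,
                 scale: Optional[LinguisticScale] = None) -> None:
    path = Path(path)
    full = {(a, b) for a in design.concepts for b in design.concepts if a != b}
    pruned = sorted(full - design.active_relationships)
    doc = {
        "schema_version": DESIGN_SCHEMA_VERSION,
        "factors": list(design.factor_names),
        "outcome": design.outcome_name,
        "intervention": {t: int(s) for t, s in design.intervention_targets.items()},
        "pruned": [list(p) for p in pruned],
        "scale": _scale_to_dict(scale or default_scale()),
    }
    text = (yaml.safe_dump(doc, sort_keys=False)
            if path.suffix in (".yaml", ".yml")
            else json.dumps(doc, indent=2))
    path.write_text(text, encoding="utf-8")


def read_design(path: str | Path) -> tuple[TrialDesign, LinguisticScale]:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
        doc = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
        design = create_trial(doc["factors"], doc["outcome"],
                              {t: int(s) for t, s in doc["intervention"].items()})
        for src, tgt in doc.get("pruned", []):
            design = prune_relationship(design, src, tgt)
        scale = (_scale_from_dict(doc["scale"]) if "scale" in doc
                 else default_scale())
    except (KeyError, TypeError, yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError(f"malformed design file {path}: {exc}") from exc
    return design, scale


# --------------------------------------------------------------------------
# Questionnaires
# --------------------------------------------------------------------------

def write_questionnaire(spec: QuestionnaireSpec, path: str | Path) -> None:
    rows = [{"item_id": i.item_id, "item_kind": i.kind, "source": i.source,
             "target": i.target, "allowed_answers": "|".join(i.choices)}
            for i in spec.items]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Responses (completed questionnaires): factor self-ratings + answers
# --------------------------------------------------------------------------

RESPONSE_COLUMNS = ["participant_id", "item_kind", "source", "target",
                    "direction", "term", "value"]


def write_responses(records: Sequence[ParticipantRecord],
                    answers: Sequence[RelationshipAnswer],
                    path: str | Path) -> None:
    rows = []
    for r in records:
        for factor in r.factor_values:
            v = r.factor_values[factor]
            rows.append({"participant_id": r.participant_id,
                         "item_kind": "factor", "source": factor, "target": "",
                         "direction": "", "term": "",
                         "value": "" if v is None else v})
    for a in answers:
        rows.append({"participant_id": a.participant_id,
                     "item_kind": "relationship", "source": a.source,
                     "target": a.target,
                     "direction": "" if a.direction is None else a.direction,
                     "term": "" if a.term is None else a.term, "value": ""})
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def read_responses(
    path: str | Path,
    scale: Optional[LinguisticScale] = None,
    design: Optional[TrialDesign] = None,
) -> tuple[list[ParticipantRecord], list[RelationshipAnswer]]:
    """Parse a responses file into participant records and answers.

    Blank cells become missing values; strength terms are validated
    against the scale (with the row number reported on failure), and
    concept labels against the design when one is given.
    """
    scale = scale or default_scale()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"cannot read responses file {path}: {exc}") from exc
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"responses file {path} lacks columns {missing_cols}")
    known = set(design.concepts) if design is not None else None
    factor_values: dict[str, dict[str, Optional[float]]] = {}
    answers: list[RelationshipAnswer] = []
    for row in df.itertuples():
        line = row.Index + 2  # header is line 1
        pid = row.participant_id
        if row.item_kind == "factor":
            try:
                value = None if row.value == "" else float(row.value)
            except ValueError:
                raise ParseError(
                    f"line {line}: factor value {row.value!r} is not numeric"
                ) from None
            if known is not None and row.source not in known:
                raise ValidationError(f"line {line}: unknown concept {row.source!r}")
            factor_values.setdefault(pid, {})[row.source] = value
        elif row.item_kind == "relationship":
            term = None if row.term == "" else row.term
            if term is not None and term != scale.unsure_token \
                    and term not in scale.terms:
                raise ParseError(f"line {line}: unknown term {term!r}")
            if known is not None and (row.source not in known
                                      or row.target not in known):
                raise ValidationError(
                    f"line {line}: unknown relationship "
                    f"{row.source!r} -> {row.target!r}"
                )
            direction = None
            if row.direction != "" and term is not None \
                    and term != scale.unsure_token:
                direction = int(float(row.direction))
            answers.append(RelationshipAnswer(
                participant_id=pid, source=row.source, target=row.target,
                term=term, direction=direction,
            ))
        else:
            raise ParseError(f"line {line}: unknown item kind {row.item_kind!r}")
    records = [ParticipantRecord(participant_id=pid, factor_values=vals)
               for pid, vals in factor_values.items()]
    return records, answers


# --------------------------------------------------------------------------
# Weight matrices
# --------------------------------------------------------------------------

def write_weight_matrix(W: WeightMatrix, path: str | Path,
                        engine_config: Optional[EngineConfig] = None) -> None:
    path = Path(path)
    pd.DataFrame(W.weights, index=list(W.concepts),
                 columns=list(W.concepts)).to_csv(path)
    meta = {"outcome": W.outcome, "intervention": W.intervention,
            "engine": asdict(engine_config or EngineConfig())}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2), encoding="utf-8")


def read_weight_matrix(path: str | Path) -> tuple[WeightMatrix, EngineConfig]:
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text(encoding="utf-8")
        )
        W = WeightMatrix(weights=df.to_numpy(), concepts=tuple(df.columns),
                         outcome=meta["outcome"],
                         intervention=meta["intervention"])
        cfg = EngineConfig(**meta.get("engine", {}))
    except (KeyError, FileNotFoundError, json.JSONDecodeError) as exc:
        raise ParseError(f"malformed weight matrix {path}: {exc}") from exc
    return W, cfg


# --------------------------------------------------------------------------
# Allocations and reports
# --------------------------------------------------------------------------

def write_allocation(alloc: Allocation, path: str | Path,
                     changes: Optional[Sequence[ExpectedChange]] = None) -> None:
    e = {c.participant_id: c.value for c in changes} if changes else {}
    rows = [{"participant_id": pid, "group": g,
             "E": e.get(pid, ""), "method": alloc.method,
             "seed": "" if alloc.seed is None else alloc.seed,
             "batch": "" if alloc.batch is None else alloc.batch.get(pid, "")}
            for pid, g in alloc.groups.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_allocation(path: str | Path) -> Allocation:
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except Exception as exc:
        raise ParseError(f"cannot read allocation file {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"allocation file {path} is empty")
    method = str(df["method"].iloc[0])
    seed = df["seed"].iloc[0]
    seed = None if pd.isna(seed) else int(seed)
    batch = None
    if "batch" in df.columns and df["batch"].notna().any():
        batch = {str(r.participant_id): int(r.batch)
                 for r in df.itertuples() if not pd.isna(r.batch)}
    return Allocation(
        groups={str(r.participant_id): int(r.group) for r in df.itertuples()},
        n_groups=int(df["group"].max()) + 1, method=method, seed=seed,
        batch=batch,
    )


def write_report(results: dict, path: str | Path,
                 extra: Optional[dict] = None) -> None:
    """Hierarchical JSON quality report: method -> groups and dispersions."""
    doc: dict = {"version": __version__, "methods": {}}
    for method, (alloc, rep) in results.items():
        doc["methods"][method] = {
            "sizes": alloc.sizes(),
            "groups": [asdict(g) for g in rep.groups],
            "sd_mean": rep.sd_mean, "sd_min": rep.sd_min, "sd_max": rep.sd_max,
            "overall_min": rep.overall_min, "overall_max": rep.overall_max,
        }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of an end-to-end allocation run."""

    design_path: str
    responses_path: str
    output_dir: str
    allocation: AllocationConfig = field(default_factory=AllocationConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    methods: tuple[str, ...] = ("fcm", "simple", "blocks", "stratified")
    log_level: str = "INFO"


def run_pipeline(config: RunConfig) -> dict:
    """responses -> weight matrix -> expected changes -> allocations ->
    quality reports, all written under the output directory with a run
    manifest sufficient to reproduce the run bit-identically."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    stage("read design")
    design, scale = read_design(config.design_path)
    stage("read responses")
    records, answers = read_responses(config.responses_path, scale, design)
    if not records:
        raise ValidationError("responses file contains no factor self-ratings")
    if config.allocation.imputation != "none":
        stage("impute")
        records = impute(records, config.allocation.imputation,
                         seed=config.allocation.seed)
    stage("build weight matrix")
    W = build_weight_matrix(design, answers, scale)
    write_weight_matrix(W, out / "weight_matrix.csv", config.engine)
    stage("simulate expected changes")
    changes = expected_changes(W, records, config.engine)
    stage("allocate and evaluate")
    acfg = config.allocation
    if acfg.n_sequences > 1:
        batches = split_batches(records, answers, acfg.n_sequences)
        alloc = allocate_sequential(batches, design, acfg, scale, config.engine)
        from .evaluation import quality
        results = {"fcm-sequential": (alloc, quality(alloc, changes))}
    else:
        strat = ([acfg.stratify_on] if acfg.stratify_on
                 else design.factor_names)
        results = compare_methods(
            records, answers, design, acfg, scale, config.engine,
            stratify_factors=strat, changes=changes,
        )
        results = {m: r for m, r in results.items()
                   if m.split(":")[0] in config.methods}
    for method, (alloc, rep) in results.items():
        safe = method.replace(":", "_").replace(" ", "_")
        write_allocation(alloc, out / f"allocation_{safe}.csv", changes)
    pair_overlap = {}
    methods = list(results)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            pair_overlap[f"{a}|{b}"] = overlap(results[a][0], results[b][0])
    stage("write report and manifest")
    write_report(results, out / "report.json", extra={"overlap": pair_overlap})
    manifest = {
        "version": __version__,
        "design": str(config.design_path),
        "responses": str(config.responses_path),
        "allocation_config": asdict(config.allocation),
        "engine_config": asdict(config.engine),
        "methods": list(config.methods),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    return {"results": results, "overlap": pair_overlap, "output_dir": str(out)}
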