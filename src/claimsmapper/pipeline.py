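"""End-to-end study orchestration.

One run performs the full two-stage design: extract the index-diagnosis
cohort, mine pre-onset medical-history rules, summarise them with a
Mapper graph, select antecedent rule(s) defining patient strata, and for
each stratum mine post-onset complication rules (again with a Mapper
graph when enough rules survive the filters).  All outputs are plain
text (CSV, GraphML, DOT, JSON) under one output directory, and a JSON
manifest written last records everything needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from ._version import __version__ as _pkg_version
from .claims_io import (
    ClaimsTable,
    CohortSpec,
    binarize,
    extract_cohort,
    read_claims,
    write_cohort_summary,
)
from .errors import ConfigError
from .mapper import MapperConfig, rule_index_matrix, run_mapper
from .mining import (
    AssociationRule,
    RuleFilterConfig,
    mine_rules,
    stratified_rules,
    write_rule_table,
)
from .synthetic import (
    PlantedRule,
    StratifiedPlantedRule,
    SyntheticConfig,
    generate_claims,
    write_ground_truth,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AntecedentPolicy:
    """How pre-onset rules are chosen as strata for the second stage.

    ``top_n`` takes the first n distinct unordered pairs of the sorted
    rule list; ``top_n_excluding`` additionally skips rules touching any
    code in ``exclude`` (e.g. the most ubiquitous category, to surface a
    different stratum); ``explicit`` passes ``pairs`` through unchanged.
    """

    kind: str = "top_n"
    n: int = 1
    exclude: frozenset[str] = frozenset()
    pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("top_n", "top_n_excluding", "explicit"):
            raise ConfigError(f"unknown antecedent policy {self.kind!r}")
        if self.kind != "explicit" and self.n < 1:
            raise ConfigError("policy n must be >= 1")


def select_antecedents(
    rules: Sequence[AssociationRule], policy: AntecedentPolicy
) -> list[tuple[str, str]]:
    """Choose stratum-defining code pairs from the sorted rule list.

    Both orientations of a pair count as one stratum (the stratum is a
    patient subset, unordered); the orientation of the first-ranked rule
    is kept.  An empty selection is logged, not an error.
    """
    if policy.kind == "explicit":
        return [tuple(p) for p in policy.pairs]
    chosen: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for r in rules:
        if policy.kind == "top_n_excluding" and (
            r.x_code in policy.exclude or r.y_code in policy.exclude
        ):
            continue
        key = frozenset((r.x_code, r.y_code))
        if key in seen:
            continue
        seen.add(key)
        chosen.append((r.x_code, r.y_code))
        if len(chosen) == policy.n:
            break
    if not chosen:
        logger.info("antecedent policy selected no strata")
    return chosen


@dataclass(frozen=True)
class PipelineConfig:
    """Full study configuration; exactly one input source must be set."""

    input_path: str | None = None
    dialect: Mapping[str, str] = field(default_factory=dict)
    synthetic: SyntheticConfig | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    pre_filter: RuleFilterConfig = field(default_factory=RuleFilterConfig)
    post_filter: RuleFilterConfig = field(default_factory=RuleFilterConfig)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    antecedents: AntecedentPolicy = field(default_factory=AntecedentPolicy)
    min_rules_for_mapper: int = 10
    outdir: str = "claimsmapper_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of input_path / synthetic must be configured"
            )
        if self.min_rules_for_mapper < 2:
            raise ConfigError("min_rules_for_mapper must be >= 2")

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        doc = dict(doc)
        kwargs: dict[str, Any] = {}
        if "input" in doc:
            inp = doc.pop("input")
            kwargs["input_path"] = inp["path"]
            kwargs["dialect"] = {
                k: v for k, v in inp.items() if k.endswith("_col")
            }
        if "synthetic" in doc:
            kwargs["synthetic"] = _synthetic_from_dict(doc.pop("synthetic"))
        if "cohort" in doc:
            kwargs["cohort"] = CohortSpec(**doc.pop("cohort"))
        for key in ("pre_filter", "post_filter"):
            if key in doc:
                kwargs[key] = RuleFilterConfig(**doc.pop(key))
        if "mapper" in doc:
            kwargs["mapper"] = MapperConfig(**doc.pop("mapper"))
        if "antecedents" in doc:
            a = dict(doc.pop("antecedents"))
            if "exclude" in a:
                a["exclude"] = frozenset(a["exclude"])
            if "pairs" in a:
                a["pairs"] = tuple(tuple(p) for p in a["pairs"])
            kwargs["antecedents"] = AntecedentPolicy(**a)
        for key in ("min_rules_for_mapper", "outdir", "log_level"):
            if key in doc:
                kwargs[key] = doc.pop(key)
        if doc:
            raise ConfigError(f"unknown config key(s): {sorted(doc)}")
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Override the synthetic generator's seed (file input: no-op)."""
        if self.synthetic is None:
            return self
        return dataclasses.replace(
            self, synthetic=dataclasses.replace(self.synthetic, seed=seed)
        )


def _synthetic_from_dict(doc: Mapping[str, Any]) -> SyntheticConfig:
    doc = dict(doc)
    planted = tuple(PlantedRule(**r) for r in doc.pop("planted_rules", []))
    strat = tuple(
        StratifiedPlantedRule(
            pre_x=s["pre_x"], pre_y=s["pre_y"], rule=PlantedRule(**s["rule"])
        )
        for s in doc.pop("stratified_rules", [])
    )
    return SyntheticConfig(planted_rules=planted, stratified_rules=strat, **doc)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class RunManifest:
    """Reproducibility record written (exactly once) at the end of a run."""

    config: dict
    seed: int | None
    cohort_size: int
    n_pre_rules: int
    strata: list[dict]
    files: list[str]
    version: str
    failure_stage: str | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _write_mapper_outputs(
    rules: Sequence[AssociationRule],
    mapper_cfg: MapperConfig,
    out: Path,
    stem: str,
    files: list[str],
) -> None:
    graph = run_mapper(rule_index_matrix(rules), mapper_cfg)
    for writer, suffix in (
        (graph.write_graphml, ".graphml"),
        (graph.write_dot, ".dot"),
        (graph.write_memberships_csv, "_nodes.csv"),
    ):
        path = out / f"{stem}{suffix}"
        writer(path)
        files.append(str(path.relative_to(out)))
    logger.info(
        "%s: %d nodes, %d edges, %d component(s)",
        stem, len(graph.nodes), len(graph.edges), len(graph.connected_components()),
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full two-stage study and write all outputs.

    The run is deterministic given the config (and seed, for synthetic
    input): rerunning yields byte-identical tables and graph files.  Any
    stage failure still produces a manifest recording the failed stage,
    then re-raises.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("claimsmapper")
    root.addHandler(log_handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    manifest = RunManifest(
        config=_jsonable(config),
        seed=config.synthetic.seed if config.synthetic else None,
        cohort_size=0,
        n_pre_rules=0,
        strata=[],
        files=[],
        version=_pkg_version,
    )
    stage = "input"
    try:
        if config.synthetic is not None:
            claims = generate_claims(config.synthetic)
            claims.to_csv(out / "claims.csv")
            write_ground_truth(config.synthetic, out / "ground_truth.json")
            manifest.files += ["claims.csv", "ground_truth.json"]
        else:
            claims = read_claims(config.input_path, config.dialect)

        stage = "cohort"
        journeys = extract_cohort(claims, config.cohort)
        manifest.cohort_size = len(journeys)
        logger.info("cohort size t = %d", len(journeys))
        write_cohort_summary(journeys, out / "cohort_summary.csv")
        manifest.files.append("cohort_summary.csv")
        if not journeys:
            raise ConfigError("empty cohort; nothing to mine")

        stage = "pre_rules"
        pre_matrix = binarize(journeys, "pre")
        pre_rules = mine_rules(pre_matrix, config.pre_filter)
        manifest.n_pre_rules = len(pre_rules)
        logger.info("pre-onset rules surviving filters: %d", len(pre_rules))
        write_rule_table(pre_rules, out / "pre_rules.csv")
        manifest.files.append("pre_rules.csv")

        stage = "pre_mapper"
        if len(pre_rules) >= config.min_rules_for_mapper:
            _write_mapper_outputs(
                pre_rules, config.mapper, out, "pre_mapper", manifest.files
            )
        else:
            logger.info(
                "Mapper skipped for pre-onset rules: %d < min_rules_for_mapper=%d",
                len(pre_rules), config.min_rules_for_mapper,
            )

        stage = "strata"
        for x, y in select_antecedents(pre_rules, config.antecedents):
            stratum_dir = out / "strata" / f"{x}__{y}"
            stratum_dir.mkdir(parents=True, exist_ok=True)
            size, rules = stratified_rules(journeys, (x, y), config.post_filter)
            write_rule_table(rules, stratum_dir / "post_rules.csv")
            rel = str((stratum_dir / "post_rules.csv").relative_to(out))
            manifest.files.append(rel)
            mapper_written = len(rules) >= config.min_rules_for_mapper
            if mapper_written:
                _write_mapper_outputs(
                    rules, config.mapper, out, f"strata/{x}__{y}/post_mapper",
                    manifest.files,
                )
            else:
                logger.info(
                    "Mapper skipped for stratum (%s, %s): %d rule(s) < %d",
                    x, y, len(rules), config.min_rules_for_mapper,
                )
            manifest.strata.append(
                {
                    "antecedent": [x, y],
                    "stratum_size": size,
                    "n_rules": len(rules),
                    "mapper_written": mapper_written,
                }
            )
    except Exception:
        manifest.failure_stage = stage
        manifest.write(out / "manifest.json")
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    manifest.files.append("manifest.json")
    manifest.write(out / "manifest.json")
    return manifest
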