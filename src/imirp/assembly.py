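"""Project orchestration, final-mutant assembly and report writing.

A project takes an input 3'UTR-like sequence, a mature-miRNA database, a
species, a set of mutation-site anchors and a mutation strategy; it
partitions the sites into independent regions, searches each region for
valid mutants, splices one selected mutant per region into the input,
globally re-verifies the assembled sequence, and writes a project-info
text file plus three CSV reports (input predictions, mutant predictions,
new sites).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .alphabet import validate_sequence
from .errors import AssemblyError, UsageError
from .mirna_db import MiRNA, filter_species, parse_mature_fasta
from .mutagenesis import (
    IndependentRegion,
    MutationSite,
    MutationStrategy,
    partition_regions,
)
from .seed_predictor import PredictedSite, predict_sites
from .validity import (
    InvalidSitePolicy,
    RegionResult,
    RegionStatus,
    diff_predictions,
    is_valid,
    process_region,
)

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "project_info.txt",
    "input_predictions.csv",
    "mutant_predictions.csv",
    "new_sites.csv",
)


@dataclass
class ProjectConfig:
    """Everything needed to re-run a project deterministically."""

    sequence: str
    mirna_fasta: str                       # FASTA text of the miRNA database
    species: str
    anchors: list[int]
    strategy: MutationStrategy = field(default_factory=MutationStrategy)
    policy: InvalidSitePolicy = field(default_factory=InvalidSitePolicy.perfect)
    gu_allowed: bool = False
    rng_seed: int = 0
    selection: str | list[int] = "first"   # "first" or one 1-based index per region
    database_name: str = "mature.fa"
    strict_type_diff: bool = False


@dataclass
class ProjectResult:
    config: ProjectConfig
    input_sequence: str
    mirnas: list[MiRNA]
    regions: list[IndependentRegion]
    region_results: list[RegionResult]
    input_sites: list[PredictedSite]
    selections: dict[int, int]             # region_id -> 1-based mutant index
    assembled_sequence: str | None
    assembled_sites: list[PredictedSite]
    new_sites: list[PredictedSite]

    @property
    def all_solved(self) -> bool:
        return all(r.status is RegionStatus.SOLVED for r in self.region_results)

    @property
    def unsolved_region_ids(self) -> list[int]:
        return [
            r.region_id for r in self.region_results
            if r.status is not RegionStatus.SOLVED
        ]

    @property
    def run_id(self) -> str:
        """Deterministic 12-hex identifier of the run configuration."""
        c = self.config
        blob = "|".join([
            c.sequence.upper(),
            ",".join(map(str, sorted(c.anchors))),
            "".join(sorted(c.strategy.allowed_bases)),
            str(c.strategy.changes_per_site),
            str(c.strategy.adjacency_required),
            ",".join(sorted(f"{t.value}:{w.value}" for t, w in
                            c.policy.invalid_classes)),
            str(c.gu_allowed),
            str(c.rng_seed),
            c.species,
        ])
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_sequence(source: str) -> str:
    """Read the input sequence from a raw string, plain-text file or
    single-record FASTA file."""
    path = Path(source)
    if path.is_file():
        text = path.read_text()
        if text.lstrip().startswith(">"):
            record = SeqIO.read(path, "fasta")
            return str(record.seq)
        return "".join(text.split())
    return "".join(source.split())


def assemble(
    input_sequence: str,
    regions: list[RegionResult],
    selections: dict[int, int],
    *,
    mirnas: list[MiRNA] | None = None,
    policy: InvalidSitePolicy | None = None,
    gu_allowed: bool = False,
    input_sites: list[PredictedSite] | None = None,
    strict_type_diff: bool = False,
) -> str:
    """Splice one selected valid mutant per region into the input sequence.

    Every solved region must have a selection (1-based index into its
    valid mutants); unsolved regions block assembly.  When ``mirnas`` and
    ``policy`` are given, the assembled sequence is re-verified globally
    (predict, diff against the input, apply the policy) and assembly
    fails closed on any banned new site — with inter-region gaps of at
    least 7 nt this cannot happen, so a failure indicates a partitioning
    bug.
    """
    problems = [
        r.region_id for r in regions
        if r.status is not RegionStatus.SOLVED or r.region_id not in selections
    ]
    if problems:
        raise UsageError(
            "cannot assemble: unsolved or unselected region(s) "
            + ", ".join(map(str, problems))
        )
    chars = list(input_sequence)
    for r in regions:
        idx = selections[r.region_id]
        if not 1 <= idx <= len(r.valid_mutants):
            raise UsageError(
                f"region {r.region_id}: selection {idx} out of range "
                f"1..{len(r.valid_mutants)}"
            )
        chosen = r.valid_mutants[idx - 1].candidate
        for pos in chosen.changed_positions:
            chars[pos - 1] = chosen.full_sequence[pos - 1]
    assembled = "".join(chars)
    if mirnas is not None and policy is not None:
        if input_sites is None:
            input_sites = predict_sites(input_sequence, mirnas, gu_allowed)
        new = diff_predictions(
            input_sites,
            predict_sites(assembled, mirnas, gu_allowed),
            strict_type=strict_type_diff,
        )
        if not is_valid(new, policy):
            banned = [s for s in new if policy.bans(s)]
            raise AssemblyError(
                "global re-verification of the assembled sequence found "
                f"banned new site(s): {banned} — this indicates a region "
                "partitioning bug"
            )
    return assembled


def _sites_frame(
    sites: list[PredictedSite], mirnas: list[MiRNA]
) -> pd.DataFrame:
    accession = {m.id: (m.accession or "") for m in mirnas}
    rows = [
        {
            "mirna_id": s.mirna_id,
            "accession": accession.get(s.mirna_id, ""),
            "site_type": s.site_type.value,
            "window_start": s.window_start,
            "window_end": s.window_end,
            "gu_used": s.gu_used,
            "gu_position": "" if s.gu_window_position is None else s.gu_window_position,
        }
        for s in sorted(sites, key=lambda s: (s.window_start, s.mirna_id))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "accession", "site_type", "window_start",
            "window_end", "gu_used", "gu_position",
        ],
    )


def parse_sites_csv(path: str | Path) -> list[PredictedSite]:
    """Read a predictions CSV back into :class:`PredictedSite` objects."""
    from .seed_predictor import SiteType

    by_label = {t.value: t for t in SiteType}
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        gu_pos = row.gu_position
        out.append(
            PredictedSite(
                window_start=int(row.window_start),
                mirna_id=str(row.mirna_id),
                site_type=by_label[str(row.site_type)],
                gu_used=bool(row.gu_used),
                gu_window_position=None if gu_pos == "" else int(gu_pos),
            )
        )
    return out


def write_reports(project: ProjectResult, out_dir: str | Path) -> list[Path]:
    """Write project_info.txt and the three CSV reports.

    Output bytes are a deterministic function of the project.  The new-
    sites table carries the run identifier so reports from different runs
    remain distinguishable after copying.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = project.config
    info = [
        f"imirp version: {__version__}",
        f"run id: {project.run_id}",
        f"database: {c.database_name}",
        f"species: {c.species}",
        f"mutation sites (anchors): {', '.join(map(str, c.anchors))}",
        f"strategy: {c.strategy.changes_per_site} "
        f"{'adjacent ' if c.strategy.adjacency_required else ''}changes/site, "
        f"bases {''.join(sorted(c.strategy.allowed_bases))}",
        "invalid site classes: "
        + (", ".join(sorted(f"{t.value} ({w.value})"
                            for t, w in c.policy.invalid_classes)) or "none"),
        f"G:U wobble in prediction: {'on' if c.gu_allowed else 'off'}",
        f"rng seed: {c.rng_seed}",
        f"regions: {len(project.regions)} "
        f"({'all solved' if project.all_solved else 'UNSOLVED: ' + ', '.join(map(str, project.unsolved_region_ids))})",
        "",
        "input sequence:",
        project.input_sequence,
        "",
        "assembled mutant sequence:",
        project.assembled_sequence or "(not assembled)",
        "",
    ]
    (out / "project_info.txt").write_text("\n".join(info))

    _sites_frame(project.input_sites, project.mirnas).to_csv(
        out / "input_predictions.csv", index=False, lineterminator="\n"
    )
    _sites_frame(project.assembled_sites, project.mirnas).to_csv(
        out / "mutant_predictions.csv", index=False, lineterminator="\n"
    )
    new_df = _sites_frame(project.new_sites, project.mirnas)
    new_df.insert(0, "run_id", project.run_id)
    new_df.to_csv(out / "new_sites.csv", index=False, lineterminator="\n")
    return [out / name for name in REPORT_FILES]


def run_project(config: ProjectConfig) -> ProjectResult:
    """Execute the full workflow: parse, partition, search, select, assemble.

    In non-interactive use the selection is "first" (the first valid
    mutant of each region) or an explicit list of 1-based indices, one
    per region.  Regions that end EXHAUSTED or EXHAUSTION_UNCERTAIN leave
    the project unassembled; the caller should surface that those regions
    need a different mutation strategy.
    """
    sequence = validate_sequence(config.sequence, "input sequence")
    if not config.anchors:
        raise UsageError("at least one mutation site must be specified")
    mirnas = filter_species(parse_mature_fasta(config.mirna_fasta), config.species)
    sites = [MutationSite(anchor=a) for a in config.anchors]
    regions = partition_regions(sites, sequence_length=len(sequence))
    input_sites = predict_sites(sequence, mirnas, config.gu_allowed)

    region_results: list[RegionResult] = []
    for region in regions:
        # Distinct per-region seed, derived from the project seed.
        region_seed = (config.rng_seed * 1000003 + region.region_id) % (2**31)
        region_results.append(
            process_region(
                region,
                config.strategy,
                config.policy,
                sequence,
                mirnas,
                gu_allowed=config.gu_allowed,
                rng_seed=region_seed,
                input_sites=input_sites,
                strict_type_diff=config.strict_type_diff,
            )
        )

    selections: dict[int, int] = {}
    if isinstance(config.selection, str):
        if config.selection != "first":
            raise UsageError(
                f"unknown selection mode {config.selection!r}; use 'first' or "
                "a list of 1-based indices"
            )
        for r in region_results:
            if r.status is RegionStatus.SOLVED:
                selections[r.region_id] = 1
    else:
        if len(config.selection) != len(region_results):
            raise UsageError(
                f"{len(region_results)} region(s) but {len(config.selection)} "
                "selection index(es)"
            )
        for r, idx in zip(region_results, config.selection):
            selections[r.region_id] = idx

    assembled = None
    assembled_sites: list[PredictedSite] = []
    new_sites: list[PredictedSite] = []
    if all(r.status is RegionStatus.SOLVED for r in region_results):
        assembled = assemble(
            sequence,
            region_results,
            selections,
            mirnas=mirnas,
            policy=config.policy,
            gu_allowed=config.gu_allowed,
            input_sites=input_sites,
            strict_type_diff=config.strict_type_diff,
        )
        assembled_sites = predict_sites(assembled, mirnas, config.gu_allowed)
        new_sites = diff_predictions(
            input_sites, assembled_sites, strict_type=config.strict_type_diff
        )

    return ProjectResult(
        config=config,
        input_sequence=sequence,
        mirnas=mirnas,
        regions=regions,
        region_results=region_results,
        input_sites=input_sites,
        selections=selections,
        assembled_sequence=assembled,
        assembled_sites=assembled_sites,
        new_sites=new_sites,
    )
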