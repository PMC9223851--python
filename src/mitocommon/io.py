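"""Haplotype table I/O and the end-to-end pipeline driver."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .haplogroups import (
    HaplogroupTree,
    assign_haplogroup,
    evaluate_panel,
    first_level_summary,
)
from .heteroplasmy import php_summary
from .matching import (
    DEFAULT_RULES,
    MatchRules,
    Scenario,
    build_identity_partition,
    is_mch,
)
from .nomenclature import Haplotype, NomenclatureError, make_haplotype, serialize_haplotype
from .reference import ReferenceGenome
from .spectrum import spectrum, spectrum_table
from .stats import forensic_params, scenario_report

REQUIRED_COLUMNS = ("sample_id", "range", "haplotype")


@dataclass
class Dataset:
    """A parsed haplotype table plus its provenance."""

    haplotypes: list[Haplotype]
    source: str = "<memory>"
    fixture_id: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [h.sample_id for h in self.haplotypes]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.haplotypes)


def _parse_range(text: str) -> tuple[int, int]:
    try:
        a, b = text.split("-")
        return int(a), int(b)
    except ValueError:
        raise ValueError(f"malformed range {text!r} (expected e.g. 1-16569)") from None


def read_haplotype_table(path: str | Path) -> Dataset:
    """Read a tab-separated haplotype table.

    Required columns: sample_id, range (e.g. ``1-16569``), haplotype
    (space-separated rCRS-relative tokens); optional: region_of_origin,
    platform.  Errors carry 1-based data row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    haplotypes = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = _parse_range(row.range)
            haplotypes.append(
                make_haplotype(
                    row.sample_id,
                    row.haplotype,
                    range_start=start,
                    range_end=end,
                    region_of_origin=getattr(row, "region_of_origin", "") or None,
                    platform=getattr(row, "platform", "") or None,
                )
            )
        except (NomenclatureError, ValueError) as e:
            raise ValueError(f"{path}: row {i}: {e}") from None
    return Dataset(haplotypes=haplotypes, source=str(path))


def write_haplotype_table(hs: Sequence[Haplotype], path: str | Path) -> None:
    rows = [
        {
            "sample_id": h.sample_id,
            "range": h.range_string,
            "haplotype": serialize_haplotype(h),
            "region_of_origin": h.region_of_origin or "",
            "platform": h.platform or "",
        }
        for h in hs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fractions_table(path: str | Path) -> dict[str, dict[int, float]]:
    """TSV with columns sample_id, position, minor_fraction."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[int, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample_id), {})[int(row.position)] = float(
            row.minor_fraction
        )
    return out


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(
    dataset: Dataset,
    tree: Optional[HaplogroupTree] = None,
    rules: MatchRules = DEFAULT_RULES,
    scenario: Scenario = Scenario.DOUBLE_MATCH,
    reference: Optional[ReferenceGenome] = None,
    out_dir: Optional[str | Path] = None,
    tie_tolerance: float = 0.0,
) -> dict:
    """Screening → partition → statistics → haplogroups → panel → PHP
    summary → spectrum, as one deterministic report bundle.

    When ``out_dir`` is given, stage outputs are also written there as
    TSV/JSON files plus an aggregate ``report.json``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    hs = dataset.haplotypes
    report: dict = {"n_samples": len(hs), "source": dataset.source}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrap

    mch_flags = {
        h.sample_id: stage("screen-mch")(is_mch, h, rules, reference)
        for h in hs
    }
    report["mch"] = {
        "n_mch": sum(mch_flags.values()),
        "fraction": sum(mch_flags.values()) / len(hs),
    }

    partition = stage("partition")(
        build_identity_partition, hs, rules, scenario, reference
    )
    params = stage("stats")(forensic_params, partition)
    report["partition"] = partition.to_dict()
    report["forensic_params"] = params.summary()
    report["scenarios"] = (
        stage("scenarios")(scenario_report, hs, rules, reference)
        .reset_index()
        .to_dict(orient="records")
    )

    if tree is None:
        from .fixtures import haplogroup_tree

        tree = haplogroup_tree()
    assignments = {
        h.sample_id: stage("assign")(
            assign_haplogroup, h, tree,
            tie_tolerance=tie_tolerance, rules=rules, reference=reference,
        ).call
        for h in hs
    }
    report["haplogroups"] = assignments
    report["first_level"] = (
        first_level_summary(assignments, tree).to_dict(orient="records")
    )

    panel_params = stage("panel")(evaluate_panel, hs, rules)
    report["panel"] = panel_params.summary()

    report["php"] = stage("php-summary")(php_summary, hs, reference)

    hist = stage("spectrum")(spectrum, hs, rules)
    table = spectrum_table(hist)
    report["spectrum"] = {
        "total_events": hist.total_events,
        "n_positions": len(hist.counts),
        "labelled": table.loc[table["label"] != "", "label"].tolist(),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "partition.json").write_text(
            json.dumps(partition.to_dict(), indent=2, sort_keys=True)
        )
        table.to_csv(out / "spectrum.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(assignments.items()), columns=["sample_id", "haplogroup"]
        ).to_csv(out / "haplogroups.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str)
        )
    return report
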