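"""End-to-end orchestration over a fixture directory.

A fixture directory (as produced by :func:`mtsomatic.simulate.write_cohort`
or assembled by hand) contains::

    reference.fasta  genes.tsv  tumour_calls.tsv  host_calls.tsv
    coverage.tsv  clades.tsv  panel.tsv

``run_pipeline`` executes filter -> classify -> spectrum -> selection ->
timing -> copy-number -> naming, writes per-stage TSV/JSON reports plus a
summary, and raises on any stage-invariant violation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import defaults
from .calls import (
    CoverageSummary,
    VariantCall,
    group_by_sample,
    read_coverage_table,
    read_variant_table,
)
from .classify import (
    ClassifiedVariantSet,
    Label,
    build_variant_classes,
    classify_with_host,
    classify_without_host,
    estimate_tumour_fraction,
    normalize_vaf,
)
from .copynumber import estimate_copy_number
from .filters import filter_indels, filter_substitutions, kept_calls
from .haplotypes import HaplotypeNamer, format_tumour_name, reconstruct_donor_haplotype
from .reference import MtReference, load_reference
from .selection import (
    count_observed_by_context,
    count_opportunities,
    dnds_fit,
    truncating_vs_other_comparisons,
)
from .spectrum import compute_spectrum
from .timing import CladeBurden, timing_report

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Thresholds and options; every numeric default is the standard value
    from :mod:`mtsomatic.defaults` and can be overridden via YAML."""

    vaf_cutoff: float = defaults.DEFAULT_VAF_CUTOFF
    vaf_cutoff_per_tumour: dict[str, float] = field(default_factory=dict)
    reference_clade: int | None = None  # nuclear-calibration clade; min-burden if None
    calibration_age_years: float = defaults.NUCLEAR_CALIBRATION_YEARS
    excluded_clades: tuple = defaults.EXCLUDED_CLADES
    presentation_rounding: bool = False
    excluded_regions: list = field(default_factory=list)
    excluded_sites: list = field(default_factory=list)
    rescue_list: list | None = None
    compute_ci: bool = False
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "excluded_clades" in kwargs:
            kwargs["excluded_clades"] = tuple(kwargs["excluded_clades"])
        return cls(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_mapping(data)


@dataclass
class PipelineResult:
    reference: MtReference
    substitution_verdicts: dict
    indel_verdicts: dict
    tumour_fractions: dict[str, float]
    classified: ClassifiedVariantSet
    spectrum: Any
    ks: dict
    dnds: Any
    timing: list
    copy_numbers: list
    haplotype_names: dict[str, str]
    summary: dict


def _read_fixture(input_dir: Path, config: PipelineConfig):
    for name in ("reference.fasta", "genes.tsv", "tumour_calls.tsv", "coverage.tsv", "clades.tsv"):
        if not (input_dir / name).exists():
            raise FileNotFoundError(f"fixture file missing: {input_dir / name}")
    ref = load_reference(
        input_dir / "reference.fasta",
        input_dir / "genes.tsv",
        {
            "excluded_regions": config.excluded_regions,
            "excluded_sites": config.excluded_sites,
        },
    )
    tumours = group_by_sample(read_variant_table(input_dir / "tumour_calls.tsv"))
    hosts_path = input_dir / "host_calls.tsv"
    hosts = group_by_sample(read_variant_table(hosts_path)) if hosts_path.exists() else {}
    coverage = read_coverage_table(input_dir / "coverage.tsv")
    clade_of: dict[str, int] = {}
    host_of: dict[str, str | None] = {}
    with open(input_dir / "clades.tsv") as fh:
        header = fh.readline()
        for line in fh:
            tumour, clade, host = (line.rstrip("\n").split("\t") + [""])[:3]
            clade_of[tumour] = int(clade)
            host_of[tumour] = host or None
    panel: set = set()
    panel_path = input_dir / "panel.tsv"
    if panel_path.exists():
        with open(panel_path) as fh:
            fh.readline()
            for line in fh:
                pos, ref_a, alt_a = line.rstrip("\n").split("\t")
                panel.add((int(pos), ref_a, alt_a))
    return ref, tumours, hosts, coverage, clade_of, host_of, panel


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    ref, tumours, hosts, coverage, clade_of, host_of, panel = _read_fixture(
        input_dir, config
    )

    # --- stage 1: filters --------------------------------------------------
    repeat_region = (
        tuple(config.excluded_regions[0])
        if config.excluded_regions
        else (ref.length + 1, ref.length + 1)  # no-op when nothing configured
    )
    sub_verdicts: dict[str, list] = {}
    indel_verdicts: dict[str, list] = {}
    kept_subs: dict[str, list[VariantCall]] = {}
    kept_indels: dict[str, list[VariantCall]] = {}
    for sample, calls in sorted({**tumours, **hosts}.items()):
        subs = [c for c in calls if not c.is_indel]
        indels = [c for c in calls if c.is_indel]
        iverdicts = filter_indels(
            indels, coverage=coverage, repeat_region=repeat_region
        )
        sverdicts = filter_substitutions(
            subs,
            ref,
            kept_calls(iverdicts),
            rescue_list=config.rescue_list or [],
            repeat_region=repeat_region,
        )
        sub_verdicts[sample] = sverdicts
        indel_verdicts[sample] = iverdicts
        kept_subs[sample] = kept_calls(sverdicts)
        kept_indels[sample] = kept_calls(iverdicts)

    # --- stage 2: somatic classification -----------------------------------
    fractions: dict[str, float] = {}
    labelled: dict[str, list[tuple[VariantCall, Label]]] = {}
    for tumour in sorted(clade_of):
        calls = kept_subs.get(tumour, []) + kept_indels.get(tumour, [])
        host = host_of.get(tumour)
        if host is not None and host in coverage:
            host_kept = kept_subs.get(host, []) + kept_indels.get(host, [])
            subs_only = [c for c in calls if not c.is_indel]
            try:
                fractions[tumour] = estimate_tumour_fraction(subs_only, host_kept)
            except ValueError:
                fractions[tumour] = 1.0
            labels = classify_with_host(calls, host_kept, coverage[host])
        else:
            cutoff = config.vaf_cutoff_per_tumour.get(tumour, config.vaf_cutoff)
            labels = classify_without_host(calls, cutoff)
            fractions[tumour] = 1.0
        labelled[tumour] = list(zip(calls, labels))

    classified = build_variant_classes(
        labelled,
        {t: c for t, c in clade_of.items() if t in labelled},
        panel,
        tumour_fractions=fractions,
        excluded_clades=config.excluded_clades,
    )

    # --- stage 3: spectrum --------------------------------------------------
    conservative_records = classified.conservative_records()
    pseudo_calls = [
        VariantCall(
            sample_id="conservative",
            position=r.key[0],
            ref=r.key[1],
            alt=r.key[2],
            kind="substitution",
            mutant_reads=1,
            total_depth=1,
            fwd_mutant=1,
            bq25_reads=1,
        )
        for r in conservative_records
    ]
    spectrum = (
        compute_spectrum(
            ref, pseudo_calls, presentation_rounding=config.presentation_rounding
        )
        if pseudo_calls
        else None
    )

    # --- stage 4: selection -------------------------------------------------
    somatic_indel_pairs = []
    for tumour, pairs in labelled.items():
        f = fractions.get(tumour, 1.0)
        for call, label in pairs:
            if call.is_indel and label.label == "somatic":
                somatic_indel_pairs.append((call, normalize_vaf(call.vaf, f)))
    ks = truncating_vs_other_comparisons(classified, ref, somatic_indel_pairs)
    dnds = None
    conservative_keys = [r.key for r in conservative_records]
    if conservative_keys:
        observed = count_observed_by_context(ref, conservative_keys)
        if any(sum(v.values()) for v in observed.values()):
            opportunities = count_opportunities(ref)
            dnds = dnds_fit(observed, opportunities, compute_ci=config.compute_ci)

    # --- stage 5: timing ----------------------------------------------------
    # burdens both without and with potential-somatic variants (the latter
    # add one shared count per clade member per potential variant)
    burdens: list[CladeBurden] = []
    for clade in classified.clades:
        members = classified.tumours_by_clade[clade]
        counts = tuple(
            sum(
                1
                for record in classified.somatic[clade].values()
                if member in record.carriers
            )
            for member in members
        )
        n_potential = len(classified.potential_somatic[clade])
        burdens.append(CladeBurden(clade=clade, per_tumour_counts=counts))
        burdens.append(
            CladeBurden(
                clade=clade,
                per_tumour_counts=tuple(c + n_potential for c in counts),
                includes_potential_somatic=True,
            )
        )
    timing = []
    for include_potential in (False, True):
        subset = [
            b
            for b in burdens
            if b.includes_potential_somatic == include_potential and b.mean > 0
        ]
        if not subset:
            continue
        if config.reference_clade is not None:
            ref_clades = [b.clade for b in subset]
            if config.reference_clade not in ref_clades:
                continue
            ref_clade = config.reference_clade
        else:
            ref_clade = min(subset, key=lambda b: b.mean).clade
        for est in timing_report(
            subset,
            reference_clade=ref_clade,
            calibration_age_years=config.calibration_age_years,
        ):
            timing.append((est, include_potential))

    # --- stage 6: copy number ----------------------------------------------
    copy_numbers = [
        estimate_copy_number(coverage[s]) for s in sorted(coverage)
    ]

    # --- stage 7: naming ----------------------------------------------------
    names: dict[str, str] = {}
    for tumour in sorted(clade_of):
        names[tumour] = format_tumour_name(clade_of[tumour]).text
    donors = {
        str(clade): sorted(reconstruct_donor_haplotype(classified, clade))
        for clade in classified.clades
    }

    summary = {
        "n_tumours": len(clade_of),
        "n_hosts": len(hosts),
        "n_conservative_somatic": len(conservative_records),
        "tumour_fractions": {k: round(v, 6) for k, v in sorted(fractions.items())},
        "clade_burdens": {
            f"{b.clade}{'+potential' if b.includes_potential_somatic else ''}":
                round(b.mean, 6)
            for b in burdens
        },
        "dnds": None
        if dnds is None
        else {
            "w_mis": round(dnds.w_mis, 6),
            "w_non": round(dnds.w_non, 6),
            "p_mis": dnds.p_mis,
            "p_non": dnds.p_non,
        },
        "ks": {
            name: None
            if comp is None
            else {"D": round(comp.statistic, 6), "p": comp.pvalue,
                  "n_a": comp.n_a, "n_b": comp.n_b}
            for name, comp in ks.items()
        },
        "donor_haplotypes": donors,
        "haplotype_names": names,
    }

    result = PipelineResult(
        reference=ref,
        substitution_verdicts=sub_verdicts,
        indel_verdicts=indel_verdicts,
        tumour_fractions=fractions,
        classified=classified,
        spectrum=spectrum,
        ks=ks,
        dnds=dnds,
        timing=timing,
        copy_numbers=copy_numbers,
        haplotype_names=names,
        summary=summary,
    )
    if output_dir is not None:
        _write_reports(result, Path(output_dir), config)
    return result


def _write_reports(result: PipelineResult, output_dir: Path, config: PipelineConfig) -> None:
    output_dir.mkdir(parents=True, exist_ok=True)

    with open(output_dir / "filter_verdicts.tsv", "w") as fh:
        fh.write("sample_id\tposition\tref\talt\tkind\tkept\treasons\n")
        for sample in sorted(result.substitution_verdicts):
            for v in (
                result.substitution_verdicts[sample] + result.indel_verdicts[sample]
            ):
                fh.write(
                    f"{v.variant.sample_id}\t{v.variant.position}\t{v.variant.ref}\t"
                    f"{v.variant.alt}\t{v.variant.kind}\t{int(v.kept)}\t"
                    f"{','.join(v.reasons)}\n"
                )

    with open(output_dir / "variant_classes.tsv", "w") as fh:
        fh.write("clade\tclass\tposition\tref\talt\n")
        c = result.classified
        for clade in c.clades:
            rows = (
                [("clade_defining_germline", k) for k in sorted(c.clade_defining[clade])]
                + [("potential_somatic", k) for k in sorted(c.potential_somatic[clade])]
                + [("somatic", k) for k in sorted(c.somatic[clade])]
                + [("conservative_somatic", k) for k in sorted(c.conservative_somatic[clade])]
            )
            for klass, key in rows:
                fh.write(f"{clade}\t{klass}\t{key[0]}\t{key[1]}\t{key[2]}\n")

    if result.spectrum is not None:
        with open(output_dir / "spectrum.tsv", "w") as fh:
            fh.write("class\tstrand\tsubstitution\ttriplet\tobserved\texpected\tnormalized_rate\n")
            for row in result.spectrum.to_rows():
                fh.write(
                    f"{row['class']}\t{row['strand']}\t{row['substitution']}\t"
                    f"{row['triplet']}\t{row['observed']}\t{row['expected']:.10g}\t"
                    f"{row['normalized_rate']:.10g}\n"
                )

    with open(output_dir / "timing.tsv", "w") as fh:
        fh.write("clade\tmethod\tincludes_potential\trate_per_year\tburden\tyears\n")
        for est, include_potential in result.timing:
            fh.write(
                f"{est.clade}\t{est.method}\t{int(include_potential)}\t"
                f"{est.rate:.10g}\t{est.burden:.10g}\t{est.years:.10g}\n"
            )

    with open(output_dir / "copy_number.tsv", "w") as fh:
        fh.write("sample_id\tmt_cov\tnucl_cov\tploidy\tcopies_per_cell\texcluded\n")
        for est in result.copy_numbers:
            fh.write(
                f"{est.sample_id}\t{est.mt_cov:.10g}\t{est.nucl_cov:.10g}\t"
                f"{est.ploidy}\t{est.copies_per_cell:.10g}\t{int(est.excluded)}\n"
            )

    with open(output_dir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(output_dir / "config_echo.json", "w") as fh:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        }
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
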