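"""End-to-end workflow: fixtures -> genotypes -> stats -> phasing -> reports.

All outputs are TSV with ``#``-prefixed metadata headers carrying the tool
version, the run seed and the checksums of the inputs, so identical inputs
and seed produce byte-identical output files.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import tables
from .haplotypes import (
    HaplotypeNameRegistry,
    breed_haplotype_table,
    clark_phase,
    haplotype_diversity,
    name_haplotype,
)
from .popgen import GenotypeTable, load_genotypes, locus_stats
from .promoter_model import parse_c_label
from .recombination import derivation_report, derivation_search
from .repeat_alleles import AlleleRegistry
from .synthetic_data import (
    PopulationSpec,
    file_checksum,
    generate_population,
    write_fixtures,
)

log = logging.getLogger("promsat")

#: used when no seed is configured: reproducibility over entropy
DEFAULT_SEED = 17


@dataclass
class RunConfig:
    outdir: Path
    genotypes: Path | None = None
    population_spec: Path | None = None
    registry: Path | None = None  # repeat-allele registry TSV
    seed: int = DEFAULT_SEED
    repeat_locus: str = "msat"
    stages: tuple[str, ...] = (
        "fixtures", "genotypes", "stats", "phase", "diversity", "recombination"
    )
    min_breed_n: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_ini(cls, path) -> "RunConfig":
        parser = configparser.ConfigParser()
        parser.optionxform = str
        with open(path) as fh:
            parser.read_file(fh)
        run = parser["run"]
        base = Path(path).parent

        def _path(key):
            return base / run[key] if key in run else None

        kwargs = dict(
            outdir=base / run.get("outdir", "promsat_out"),
            genotypes=_path("genotypes"),
            population_spec=_path("population_spec"),
            registry=_path("registry"),
            seed=run.getint("seed", DEFAULT_SEED),
            repeat_locus=run.get("repeat_locus", "msat"),
            min_breed_n=run.getint("min_breed_n", 5),
            log_level=run.get("log_level", "INFO"),
        )
        if "stages" in run:
            kwargs["stages"] = tuple(
                s.strip() for s in run["stages"].split(",") if s.strip()
            )
        return cls(**kwargs)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _write_tsv(df, path: Path, meta: dict) -> None:
    with open(path, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def study_name_registry(loci, repeat_locus) -> HaplotypeNameRegistry | None:
    """Name registry for the study loci, seeded from the reference pattern
    plus the haplotype numbers whose defining states are known
    (*3: the -185 T deletion; *8: the -408 G)."""
    table = tables.study_variant_table()
    ref_by_label = {}
    for rec in table.records:
        label = f"c.{rec.c_position}"
        ref_by_label.setdefault(label, rec.ref_allele)
    reference = {}
    for locus in loci:
        if locus == repeat_locus:
            continue
        try:
            c_pos = parse_c_label(locus)
        except Exception:
            return None
        if f"c.{c_pos}" not in ref_by_label:
            return None
        reference[locus] = ref_by_label[f"c.{c_pos}"]
    extra = {}
    if "c.-185" in reference:
        extra[frozenset({("c.-185", "-")})] = 3
    if "c.-408" in reference:
        extra[frozenset({("c.-408", "G")})] = 8
    try:
        return HaplotypeNameRegistry.from_reference(
            loci, repeat_locus, reference, extra_numbers=extra
        )
    except Exception:
        return None


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the configured stages; returns {output name: path}.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=cfg.log_level)
    import pandas as pd

    from . import __version__

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    meta: dict[str, object] = {"promsat_version": __version__, "seed": cfg.seed}
    summary: dict[str, object] = {}

    registry = (
        tables.study_repeat_registry() if cfg.registry is None
        else AlleleRegistry.from_tsv(cfg.registry)
    )
    if cfg.registry is not None:
        meta["registry_sha256"] = file_checksum(cfg.registry)

    if "fixtures" in cfg.stages:
        log.info("stage fixtures: exporting packaged study tables")
        checksums = write_fixtures(cfg.outdir / "fixtures")
        for name, digest in checksums.items():
            meta[f"fixture_{name}"] = digest
            outputs[f"fixtures/{name}"] = cfg.outdir / "fixtures" / name
        vt = tables.study_variant_table()
        summary["variant_rows"] = len(vt.records)
        summary["variant_loci"] = len(vt.loci)
        summary["snp_loci"] = vt.count_loci(
            {"substitution", "single_base_deletion"}
        )
        for species in ("dog", "wolf", "coyote"):
            lengths = sorted(registry.distinct_lengths(species))
            summary[f"repeat_lengths_{species}"] = ",".join(map(str, lengths))

    table: GenotypeTable | None = None
    if "genotypes" in cfg.stages:
        try:
            if cfg.population_spec is not None:
                spec = PopulationSpec.from_ini(cfg.population_spec)
                spec.seed = cfg.seed
                meta["population_spec_sha256"] = file_checksum(
                    cfg.population_spec
                )
                log.info(
                    "stage genotypes: simulating %d individuals (seed %d)",
                    spec.n_individuals, spec.seed,
                )
                sim = generate_population(spec, registry=registry)
                table = sim.table
                summary["n_slipped_transmissions"] = sim.n_slipped
            elif cfg.genotypes is not None:
                meta["genotypes_sha256"] = file_checksum(cfg.genotypes)
                log.info("stage genotypes: loading %s", cfg.genotypes)
                table = load_genotypes(
                    cfg.genotypes, repeat_locus=cfg.repeat_locus,
                    registry=registry,
                )
        except Exception as err:
            raise PipelineError(f"stage genotypes: {err}") from err
        if table is not None:
            from .popgen import write_genotypes

            path = cfg.outdir / "genotypes.tsv"
            write_genotypes(
                table, path,
                header_comment="\n".join(f"{k}: {v}" for k, v in meta.items()),
            )
            outputs["genotypes"] = path
            summary["n_individuals"] = len(table)

    if table is not None and "stats" in cfg.stages:
        try:
            rows = []
            for locus in table.loci:
                st = locus_stats(table, locus)
                rows.append({
                    "locus": st.locus,
                    "alleles": ",".join(st.allele_counts),
                    "counts": ",".join(map(str, st.allele_counts.values())),
                    "maf": round(st.maf, 4),
                    "hwe_chi2": round(st.hwe_chi2, 4),
                    "hwe_df": st.hwe_df,
                })
            df = pd.DataFrame(rows).set_index("locus")
            path = cfg.outdir / "locus_stats.tsv"
            _write_tsv(df, path, meta)
            outputs["locus_stats"] = path
        except Exception as err:
            raise PipelineError(f"stage stats: {err}") from err

    phased = None
    if table is not None and "phase" in cfg.stages:
        try:
            phased = clark_phase(table, seed=cfg.seed)
            name_registry = study_name_registry(
                tuple(table.loci), cfg.repeat_locus
            )
            if name_registry is not None:
                for hap in phased.haplotypes:
                    name_haplotype(hap, name_registry)
            freqs = phased.frequencies()
            df = pd.DataFrame([
                {
                    "haplotype": h.name or h.state_string,
                    "states": h.state_string,
                    "frequency": round(freqs[h], 4),
                    "support": h.support,
                }
                for h in phased.haplotypes
            ]).set_index("haplotype")
            path = cfg.outdir / "haplotypes.tsv"
            _write_tsv(df, path, meta)
            outputs["haplotypes"] = path

            dip_df = pd.DataFrame([
                {
                    "id": d.individual.id,
                    "breed": d.individual.breed,
                    "phased": "|".join(
                        h.name or h.state_string for h in d.haplotypes
                    ),
                    "resolution": d.resolution,
                }
                for d in phased.diplotypes
            ]).set_index("id")
            path = cfg.outdir / "diplotypes.tsv"
            _write_tsv(dip_df, path, meta)
            outputs["diplotypes"] = path
            summary["n_haplotypes"] = len(phased.haplotypes)
            summary["n_unresolved"] = len(phased.unresolved)
        except Exception as err:
            raise PipelineError(f"stage phase: {err}") from err

    if phased is not None and "diversity" in cfg.stages:
        try:
            n_chrom = 2 * len(phased.diplotypes)
            freqs = phased.frequencies()
            summary["H_overall"] = round(
                haplotype_diversity(list(freqs.values()), n_chrom), 4
            )
            freq_table, diversity = breed_haplotype_table(
                phased.diplotypes, min_breed_n=cfg.min_breed_n
            )
            if len(freq_table):
                freq_table["H"] = diversity.round(4)
                path = cfg.outdir / "breed_haplotypes.tsv"
                _write_tsv(freq_table.round(4), path, meta)
                outputs["breed_haplotypes"] = path
        except Exception as err:
            raise PipelineError(f"stage diversity: {err}") from err

    if "recombination" in cfg.stages:
        try:
            frames = []
            for allele in registry:
                if allele.remainder:
                    continue
                derivations = derivation_search(
                    allele, registry, match_mode="sequence"
                )
                nontrivial = [
                    d for d in derivations if d.event.offset != 0
                ]
                if nontrivial:
                    frames.append(derivation_report(nontrivial))
            df = (
                pd.concat(frames, ignore_index=True) if frames
                else derivation_report([])
            )
            path = cfg.outdir / "derivations.tsv"
            _write_tsv(df, path, meta)
            outputs["derivations"] = path
            summary["n_sequence_derivations"] = len(df)
        except Exception as err:
            raise PipelineError(f"stage recombination: {err}") from err

    summary_df = pd.DataFrame(
        sorted(summary.items()), columns=["key", "value"]
    ).set_index("key")
    path = cfg.outdir / "summary.tsv"
    _write_tsv(summary_df, path, meta)
    outputs["summary"] = path
    return outputs
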