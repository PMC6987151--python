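"""One-shot "full dossier" run over a synthetic event.

Sequences the stages in results order: Southern fragment prediction,
insertion-site sequence characterization and junction ORF scan, allergen
and toxin screens of the junction ORF peptides, dietary-exposure
estimation, and Mendelian segregation testing.  Every output is a TSV or
JSON file with a commented header naming the package version, seed and
config hash, and re-running with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .digest_map import get_enzymes, predict_southern, southern_table
from .errors import DataError
from .junction import characterize_borders, junction_spanning_orfs
from .riskcalc import (
    ExposureInputs, chi2_critical, daily_intake, dietary_exposure, segregation_report,
)
from .screen import ScreenConfig, allergen_screen, calibrate_evalue, hits_to_rows, toxin_screen
from .seqcore import SequenceRecord, write_fasta
from .synth import (
    GR2E_EXPRESSION_MEANS, EventBundle, gr2e_bundle, gr2e_probes,
    make_expression_table, make_protein_db, make_segregation_panel, write_panel_tsv,
)

#: Digests run for the Southern stage: two single-cutter copy-number
#: digests and the double digest that releases the internal fragment.
SOUTHERN_DIGESTS = (("HindIII",), ("SphI",), ("AscI", "XmaI"))

#: Segregating generations analyzed for Mendelian inheritance, with the
#: expected ratio (hemizygous parents self to 1:2:1, backcross to 1:1)
#: and the synthetic panel size used here.
SEGREGATION_GENERATIONS = (
    ("BC4F2", (1, 2, 1), 300),
    ("BC5F1", (1, 1), 200),
    ("BC5F2", (1, 2, 1), 300),
)

#: Dietary-exposure assumption set: upper-bound daily rice intake of
#: 12.5 g/kg body weight, all of it from the transgenic event, at the
#: highest measured grain concentration (dough stage).
EXPOSURE_INTAKE_G_PER_KG = 12.5


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int
    outdir: Path
    screen_dbs: bool = True  # generate synthetic screening databases
    min_aa: int = 30
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    n_shuffles: int = 100
    allergen_db_size: int = 60
    toxin_db_size: int = 60

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items() if k != "outdir"},
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


def _header(cfg: RunConfig) -> str:
    return f"# eventscreen v{__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as handle:
        handle.write(_header(cfg))
        df.to_csv(handle, sep="\t", index=False)


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    payload = {"_meta": {"version": __version__, "seed": cfg.seed,
                         "config": cfg.config_hash()}, **obj}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DataError as exc:
                raise DataError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


@_stage("southern")
def southern_stage(bundle: EventBundle, cfg: RunConfig, outdir: Path) -> dict:
    probes = gr2e_probes(bundle)
    rows = []
    per_probe_counts: dict[str, list[int]] = {p.name: [] for p in probes}
    for enzyme_names in SOUTHERN_DIGESTS:
        enzymes = get_enzymes(enzyme_names)
        rows.extend(southern_table(bundle.event, enzymes, probes))
        predicted = predict_southern(bundle.event, enzymes, probes)
        for probe, lengths in predicted.items():
            per_probe_counts[probe].append(len(lengths))
    _write_tsv(pd.DataFrame(rows), outdir / "southern.tsv", cfg)
    gene_probes = [p.name for p in probes if p.name != "backbone"]
    asc_xma = predict_southern(bundle.event, get_enzymes(("AscI", "XmaI")), probes)
    return {
        "single_fragment_per_gene_probe": all(
            all(c == 1 for c in per_probe_counts[name]) for name in gene_probes
        ),
        "backbone_fragments": sum(per_probe_counts["backbone"]),
        "internal_fragment_bp": {
            name: asc_xma[name] for name in gene_probes
        },
    }


@_stage("junctions")
def junction_stage(bundle: EventBundle, cfg: RunConfig, outdir: Path) -> dict:
    event = characterize_borders(bundle.host, bundle.tdna, bundle.event)
    orfs = junction_spanning_orfs(event, cfg.min_aa)
    _write_json({"geometry": event.geometry_dict()}, outdir / "geometry.json", cfg)
    orf_rows = [
        {"orf": f"ORF-{i}", "strand": h.strand, "frame": h.frame, "start": h.start,
         "end": h.end, "length_bp": h.length_bp, "length_aa": h.length_aa,
         "spans": "+".join(sorted(h.spans))}
        for i, h in enumerate(orfs, start=1)
    ]
    _write_tsv(pd.DataFrame(orf_rows), outdir / "junction_orfs.tsv", cfg)
    peptides = [
        SequenceRecord(f"ORF-{i}", h.peptide, "protein")
        for i, h in enumerate(orfs, start=1)
    ]
    if peptides:
        write_fasta(peptides, outdir / "junction_orfs.fasta")
    return {"geometry": event.geometry_dict(), "orfs": orfs, "peptides": peptides}


@_stage("screens")
def screen_stage(peptides: list[SequenceRecord], cfg: RunConfig, outdir: Path) -> dict:
    allergen_db, _ = make_protein_db(
        seed=cfg.seed + 101, n_entries=cfg.allergen_db_size, length_range=(80, 200)
    )
    toxin_db, _ = make_protein_db(
        seed=cfg.seed + 202, n_entries=cfg.toxin_db_size, length_range=(100, 250)
    )
    write_fasta(allergen_db, outdir / "allergen_db.fasta")
    write_fasta(toxin_db, outdir / "toxin_db.fasta")
    allergen_rows, toxin_rows = [], []
    verdicts = {}
    for pep in peptides:
        report = allergen_screen(pep, allergen_db, cfg.screen)
        allergen_rows.extend(hits_to_rows(report.window_hits + report.kmer_hits))
        cal = calibrate_evalue(pep, toxin_db, cfg.screen,
                               n_shuffles=cfg.n_shuffles, seed=cfg.seed + 303)
        tox_hits = toxin_screen(pep, toxin_db, cfg.screen, cal)
        toxin_rows.extend(hits_to_rows(tox_hits))
        verdicts[pep.id] = {
            "allergen_flag": report.flag,
            "window80_flag": report.flagged_window80,
            "kmer8_flag": report.flagged_kmer8,
            "toxin_significant_hits": sum(h.passed for h in tox_hits),
        }
    _write_tsv(pd.DataFrame(allergen_rows), outdir / "allergen_screen.tsv", cfg)
    _write_tsv(pd.DataFrame(toxin_rows), outdir / "toxin_screen.tsv", cfg)
    _write_json({"verdicts": verdicts}, outdir / "screen_summary.json", cfg)
    return {"run": True, "verdicts": verdicts}


@_stage("exposure")
def exposure_stage(cfg: RunConfig, outdir: Path) -> dict:
    table = make_expression_table(cfg.seed + 404, GR2E_EXPRESSION_MEANS, cv=0.15)
    _write_tsv(table, outdir / "expression.tsv", cfg)
    rows = []
    exposures = {}
    for protein in ("ZmPSY1", "CRTI", "PMI"):
        conc = GR2E_EXPRESSION_MEANS[(protein, "dough")]
        est = dietary_exposure(protein, conc, EXPOSURE_INTAKE_G_PER_KG)
        exposures[protein] = est.exposure_rounded
        rows.append({
            "protein": protein, "concentration_ng_per_g": conc,
            "daily_intake_g_per_kg": est.daily_intake_rounded,
            "exposure_ug_per_kg_bw": est.exposure_rounded,
        })
    _write_tsv(pd.DataFrame(rows), outdir / "exposure.tsv", cfg)
    return {"exposures_ug_per_kg_bw": exposures}


@_stage("segregation")
def segregation_stage(cfg: RunConfig, outdir: Path) -> dict:
    rows = []
    rejects = 0
    for i, (generation, ratio, n_plants) in enumerate(SEGREGATION_GENERATIONS):
        patterns, _ = make_segregation_panel(cfg.seed + 505 + i, n_plants, ratio)
        write_panel_tsv(patterns, outdir / f"panel_{generation}.tsv")
        report = segregation_report(patterns, ratio, generation)
        rejects += report["reject"]
        rows.append({
            "generation": generation,
            "counts": ":".join(str(c) for c in report["counts"]),
            "expected_ratio": ":".join(str(r) for r in ratio),
            "chi_square": round(report["chi_square"], 3),
            "df": report["df"],
            "critical_value": round(report["critical_value"], 2),
            "reject": report["reject"],
        })
    _write_tsv(pd.DataFrame(rows), outdir / "segregation.tsv", cfg)
    return {"rejections": int(rejects), "n_generations": len(SEGREGATION_GENERATIONS),
            "critical_value_df1": round(chi2_critical(1), 2)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage over the seeded preset event; returns the summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = gr2e_bundle(cfg.seed)
    bundle.write(outdir / "event")

    southern = southern_stage(bundle, cfg, outdir)
    junctions = junction_stage(bundle, cfg, outdir)
    if cfg.screen_dbs:
        screens = screen_stage(junctions["peptides"], cfg, outdir)
    else:
        screens = {"run": False, "status": "not run (no screening databases)"}
    exposure = exposure_stage(cfg, outdir)
    segregation = segregation_stage(cfg, outdir)

    summary = {
        "southern": southern,
        "geometry": junctions["geometry"],
        "n_junction_orfs": len(junctions["orfs"]),
        "junction_orfs": [
            {"strand": h.strand, "length_bp": h.length_bp, "length_aa": h.length_aa,
             "spans": sorted(h.spans)}
            for h in junctions["orfs"]
        ],
        "screens": {k: v for k, v in screens.items() if k != "peptides"},
        "exposure": exposure,
        "segregation": segregation,
    }
    _write_json(summary, outdir / "summary.json", cfg)
    return summary
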