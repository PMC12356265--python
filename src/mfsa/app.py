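"""Command-line interface tying the workflow stages together.

Subcommands mirror the pipeline: build-library, simulate, recognize,
assign, label, annotate, plus a small convert utility.  Every run
writes a JSON parameter manifest next to its outputs so results can be
reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import sys
from importlib import resources
from pathlib import Path

import click
import pandas as pd

from mfsa import __version__
from mfsa.assembly_ranking import annotate as run_annotate
from mfsa.assembly_ranking import load_rules_config
from mfsa.formula_adduct import (
    assign_precursor,
    build_formula_db,
    load_adducts,
)
from mfsa.labeling import label_feature_ions, label_neutral_losses
from mfsa.pseudo_library import (
    NEUTRAL_LOSS,
    PRODUCT_ION,
    enumerate_library,
    load_library,
    load_module_config,
    persist_library,
)
from mfsa.recognition import RecognitionRule, recognize
from mfsa.spectra_io import (
    read_mgf,
    read_quant_csv,
    write_mgf,
    write_quant_csv,
)
from mfsa.synthetic_fixtures import SimulationConfig, simulate_dataset

logger = logging.getLogger("mfsa")


def packaged_data(name: str) -> Path:
    return Path(str(resources.files("mfsa") / "data" / name))


def _write_manifest(out_dir: Path, command: str, params: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"tool": "mfsa", "version": __version__, "command": command,
                "parameters": params}
    with (out_dir / "run_manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(path: str, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise click.ClickException(f"{what} not found: {p}")
    return p


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable debug logging.")
@click.version_option(__version__)
def cli(verbose: bool) -> None:
    """Modular fragmentation-based structure assembly for MS/MS annotation."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command("build-library")
@click.option("--modules", "modules_path", default=None,
              help="Module-set YAML (default: packaged daphnane toy set).")
@click.option("--out", "out_path", required=True, help="Output SQLite library.")
def build_library_cmd(modules_path: str | None, out_path: str) -> None:
    """Enumerate the pseudo-compound library and persist it."""
    path = _require(modules_path, "module set") if modules_path else packaged_data(
        "daphnane_modules.yaml"
    )
    ms, templates = load_module_config(path)
    lib = enumerate_library(ms, templates)
    persist_library(lib, out_path)
    _write_manifest(Path(out_path).parent, "build-library",
                    {"modules": str(path), "out": out_path})
    click.echo(
        f"library {ms.name}: {len(lib)} compounds "
        f"(slots {ms.slot_sizes}, {sum(len(v) for v in lib.duplicates.values())} "
        f"duplicates collapsed) -> {out_path}"
    )


@cli.command("simulate")
@click.option("--library", "library_path", required=True)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-members", default=50, show_default=True, type=int)
@click.option("--n-decoys", default=50, show_default=True, type=int)
@click.option("--ppm-sigma", default=1.0, show_default=True, type=float)
@click.option("--dropout", default=0.0, show_default=True, type=float)
@click.option("--out", "out_dir", required=True)
def simulate_cmd(library_path, seed, n_members, n_decoys, ppm_sigma, dropout, out_dir):
    """Emit a synthetic quant CSV + MGF + truth table."""
    lib = load_library(_require(library_path, "library"))
    cfg = SimulationConfig(
        seed=seed, n_members=n_members, n_decoys=n_decoys,
        ppm_sigma=ppm_sigma, dropout=dropout,
    )
    table, spectra, truth = simulate_dataset(lib, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_quant_csv(table, out / "quant.csv")
    write_mgf(spectra, out / "spectra.mgf")
    truth.to_csv(out / "truth.csv", index=False)
    _write_manifest(out, "simulate", {
        "library": library_path, "seed": seed, "n_members": n_members,
        "n_decoys": n_decoys, "ppm_sigma": ppm_sigma, "dropout": dropout,
    })
    click.echo(f"wrote {len(table)} features ({n_members} members) to {out}")


def _load_rules(rules_path: str | None, lib):
    path = _require(rules_path, "rules file") if rules_path else packaged_data(
        "daphnane_rules.yaml"
    )
    return load_rules_config(path, lib), path


@cli.command("recognize")
@click.option("--library", "library_path", required=True)
@click.option("--mgf", "mgf_path", required=True)
@click.option("--rules", "rules_path", default=None)
@click.option("--out", "out_path", required=True)
def recognize_cmd(library_path, mgf_path, rules_path, out_path):
    """List spectra matching the library's diagnostic-ion formulas."""
    lib = load_library(_require(library_path, "library"))
    cfg, rules_file = _load_rules(rules_path, lib)
    spectra = read_mgf(_require(mgf_path, "MGF file"))
    rule = RecognitionRule(
        formulas=tuple(lib.product_ion_formulas()),
        tol_ppm=cfg.tol_ppm,
        mz_range=cfg.normalization_range,
        noise_threshold=cfg.noise_threshold,
        min_matching_ions=cfg.min_matching_ions,
    )
    rows = []
    for s in spectra:
        hit = recognize(s, rule)
        if hit is not None:
            rows.append({
                "feature_id": hit.feature_id,
                "match_count": hit.match_count,
                "matched_formulas": ";".join(
                    m.formula.to_string() for m in hit.matches
                ),
            })
    frame = pd.DataFrame(rows, columns=["feature_id", "match_count", "matched_formulas"])
    frame.to_csv(out_path, index=False)
    _write_manifest(Path(out_path).parent, "recognize", {
        "library": library_path, "mgf": mgf_path, "rules": str(rules_file),
    })
    click.echo(f"{len(frame)}/{len(spectra)} spectra recognized -> {out_path}")


@cli.command("assign")
@click.option("--mz", required=True, type=float)
@click.option("--polarity", default="pos", type=click.Choice(["pos", "neg"]))
@click.option("--library", "library_path", default=None,
              help="Library providing the rules defaults (optional).")
@click.option("--rules", "rules_path", default=None)
@click.option("--adducts", "adducts_path", default=None)
def assign_cmd(mz, polarity, library_path, rules_path, adducts_path):
    """De novo formula/adduct assignment for a precursor m/z."""
    if library_path:
        lib = load_library(_require(library_path, "library"))
        cfg, _ = _load_rules(rules_path, lib)
    else:
        from mfsa.assembly_ranking import RulesConfig

        cfg = RulesConfig(rules=[])  # only the numeric defaults are used
    db = build_formula_db(cfg.formula_ranges)
    adducts = load_adducts(adducts_path)
    best, alternatives = assign_precursor(
        mz, polarity, db, adducts, tol_ppm=cfg.tol_ppm, rdbe_range=cfg.rdbe_range
    )
    if best is None:
        click.echo("no formula within tolerance")
        return
    click.echo(
        f"{best.neutral.to_string()} via {best.adduct} "
        f"(theo {best.theoretical_mz:.5f}, {best.ppm:+.2f} ppm, RDBE {best.rdbe:.1f})"
    )
    for alt in alternatives:
        click.echo(
            f"  alt: {alt.neutral.to_string()} via {alt.adduct} ({alt.ppm:+.2f} ppm)"
        )


@cli.command("label")
@click.option("--library", "library_path", required=True)
@click.option("--mgf", "mgf_path", required=True)
@click.option("--rules", "rules_path", default=None)
@click.option("--out", "out_path", required=True)
def label_cmd(library_path, mgf_path, rules_path, out_path):
    """Export neutral-loss and feature-ion labels as CSV."""
    lib = load_library(_require(library_path, "library"))
    cfg, rules_file = _load_rules(rules_path, lib)
    spectra = read_mgf(_require(mgf_path, "MGF file"))
    db = build_formula_db(cfg.formula_ranges)
    rows = []
    for s in spectra:
        for t in lib.templates:
            mz_range = t.mz_range or cfg.normalization_range
            if t.kind == PRODUCT_ION:
                formulas = sorted(
                    {
                        c.ion(t.id).formula.to_string(): c.ion(t.id).formula
                        for c in lib.compounds
                    }.items()
                )
                for lbl in label_feature_ions(
                    s, mz_range, [f for _, f in formulas],
                    top_n=cfg.feature_top_n, tol_ppm=cfg.tol_ppm,
                    noise_threshold=cfg.noise_threshold,
                ):
                    rows.append({
                        "feature_id": s.feature_id, "label_type": "feature_ion",
                        "family": t.id, "formula": lbl.formula.to_string(),
                        "score": round(lbl.score, 6),
                    })
            elif t.kind == NEUTRAL_LOSS:
                losses = sorted(
                    {
                        c.ion(t.id).formula.to_string(): c.ion(t.id).formula
                        for c in lib.compounds
                    }.items()
                )
                for lbl in label_neutral_losses(
                    s, mz_range, [f for _, f in losses], db,
                    c_hi=t.c_hi, c_lo=t.c_lo, tol_ppm=cfg.tol_ppm,
                    noise_threshold=cfg.noise_threshold,
                ):
                    rows.append({
                        "feature_id": s.feature_id, "label_type": "neutral_loss",
                        "family": t.id, "formula": lbl.loss.to_string(),
                        "score": round(lbl.score, 6),
                    })
    frame = pd.DataFrame(
        rows, columns=["feature_id", "label_type", "family", "formula", "score"]
    )
    frame.to_csv(out_path, index=False)
    _write_manifest(Path(out_path).parent, "label", {
        "library": library_path, "mgf": mgf_path, "rules": str(rules_file),
    })
    click.echo(f"{len(frame)} labels -> {out_path}")


@cli.command("annotate")
@click.option("--csv", "csv_path", required=True)
@click.option("--mgf", "mgf_path", required=True)
@click.option("--library", "library_path", required=True)
@click.option("--rules", "rules_path", default=None)
@click.option("--top-n", "top_n", default=None, type=int)
@click.option("--out", "out_dir", required=True)
def annotate_cmd(csv_path, mgf_path, library_path, rules_path, top_n, out_dir):
    """Run the full recognition -> labeling -> ranking pipeline."""
    lib = load_library(_require(library_path, "library"))
    cfg, rules_file = _load_rules(rules_path, lib)
    if top_n is not None:
        cfg.top_n = top_n
    table = read_quant_csv(_require(csv_path, "quant CSV"))
    spectra = read_mgf(_require(mgf_path, "MGF file"))
    report = run_annotate(table, spectra, lib, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.write_csv(out / "report.csv")
    annotated = []
    top_by_id = {}
    for fid in report.recognized_ids:
        row = report.top1(fid)
        if row is not None and row["status"] == "annotated":
            top_by_id[fid] = f"rank1 {row['compound_id']} {row['smiles']}"
    for s in spectra:
        if s.feature_id in top_by_id:
            annotated.append(
                type(s)(
                    feature_id=s.feature_id, precursor_mz=s.precursor_mz,
                    charge=s.charge, rt=s.rt, peaks=s.peaks, polarity=s.polarity,
                    annotations=(top_by_id[s.feature_id],),
                )
            )
    write_mgf(annotated, out / "annotated.mgf")
    _write_manifest(out, "annotate", {
        "csv": csv_path, "mgf": mgf_path, "library": library_path,
        "rules": str(rules_file), "top_n": cfg.top_n,
    })
    click.echo(
        f"{len(report.recognized_ids)} features recognized, report -> {out / 'report.csv'}"
    )


@cli.command("convert")
@click.option("--mgf", "mgf_path", required=True)
@click.option("--out", "out_path", required=True)
def convert_cmd(mgf_path, out_path):
    """Normalize an MGF file (sorted peaks, canonical headers)."""
    spectra = read_mgf(_require(mgf_path, "MGF file"))
    write_mgf(spectra, out_path)
    click.echo(f"rewrote {len(spectra)} spectra -> {out_path}")


if __name__ == "__main__":  # pragma: no cover
    cli()
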