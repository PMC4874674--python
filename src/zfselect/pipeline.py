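"""End-to-end orchestration: route, decompose, catalogue, scan, select.

Stage order mirrors the bench workflow for a mixed PRDM9/PRDM7 amplicon
panel: paralog assignment first (PRDM7-like records go only to the
disruption scan), then array decomposition, domain catalogue and genotype
summaries, and finally site-model selection analyses run for each species
separately and for all species pooled.  A failure in one record halts its
own downstream stages, not the rest of the panel.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import seq_io
from .seq_io import SequenceRecord, classify_paralog
from .trees import Tree, parse_newick, write_newick
from .zf_decompose import (
    ZFArray,
    segment_array,
    decomposition_table,
    NotAZFArrayError,
)
from .domain_catalog import (
    GenotypeRecord,
    build_catalog,
    array_schematic,
    cross_species_stats,
    genotype_summary,
)
from .pseudogene_scan import scan_orf, detect_frameshift, disruption_table
from .codon_model import CodonLikelihood
from .site_selection import (
    build_codon_alignment,
    nj_tree,
    optimize_branch_lengths,
    fit_site_model,
    lrt,
    beb_classify,
    lrt_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "select_group"]

DEFAULT_MODELS = ("M1a", "M2a", "M7", "M8")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, in one place."""

    records: list[SequenceRecord] = field(default_factory=list)
    input_fasta: list[str] = field(default_factory=list)
    species_map: dict[str, str] | None = None  # regex pattern -> species
    refs: list[SequenceRecord] = field(default_factory=list)
    tree_newick: str | None = None
    models: tuple[str, ...] = DEFAULT_MODELS
    significance: tuple[float, float] = (0.05, 0.01)
    out_dir: str | None = None
    seed: int = 1
    strict_equal_length: bool = False
    include_first_finger: bool = False
    min_taxa: int = 3
    n_starts: int = 3

    def __post_init__(self) -> None:
        a, b = self.significance
        if not (0 < b < a < 1):
            raise ValueError("significance thresholds must be descending in (0,1)")


@dataclass
class PipelineResult:
    arrays: list[ZFArray]
    catalog: object
    genotypes: pd.DataFrame | None
    disruption: pd.DataFrame
    lrt_results: dict[str, dict[str, object]]
    beb_flagged: dict[str, list[int]]
    fits: dict[str, dict[str, object]]
    errors: list[str]
    manifest: dict


def _resolve_species(record_id: str, species_map: dict[str, str] | None) -> str | None:
    if species_map:
        for pattern, species in species_map.items():
            if re.search(pattern, record_id):
                return species
        return None
    return re.split(r"[|_]", record_id)[0] or None


def _dedupe_arrays(arrays: list[ZFArray]) -> list[ZFArray]:
    """One representative per distinct unit-sequence haplotype."""
    seen, out = set(), []
    for arr in sorted(arrays, key=lambda a: a.record_id):
        key = "".join(u.nt for u in arr.units)
        if key not in seen:
            seen.add(key)
            out.append(arr)
    return out


def select_group(arrays: list[ZFArray], config: PipelineConfig,
                 tree: Tree | None = None):
    """Site-model fits, LRTs and BEB for one taxon group.

    Returns ``(fits, lrts, flagged_helix_positions)``.  The tree is
    neighbor-joining on codon p-distances unless supplied; branch lengths are
    ML-optimized under M0 and then held fixed for every site-model fit.
    """
    aln = build_codon_alignment(
        arrays,
        include_first_finger=config.include_first_finger,
        strict_equal_length=config.strict_equal_length,
    )
    if tree is None:
        tree = nj_tree(aln)
    fit0 = fit_site_model(aln, tree, "M0", n_starts=1, seed=config.seed)
    cl = CodonLikelihood(aln.codes, tree, aln.taxa)
    optimize_branch_lengths(cl, fit0.kappa, fit0.params["omega"])
    # write optimized lengths back onto the tree for all later fits
    _apply_lengths(tree, cl)

    fits: dict[str, object] = {"M0": fit0}
    for model in config.models:
        null = {"M2a": "M1a", "M8": "M7"}.get(model)
        null_fit = fits.get(null) if null else None
        fits[model] = fit_site_model(
            aln, tree, model, n_starts=config.n_starts, seed=config.seed,
            null_fit=null_fit,
        )
    lrts = {}
    if "M1a" in fits and "M2a" in fits:
        lrts["M2a_vs_M1a"] = lrt(fits["M1a"], fits["M2a"])
    if "M7" in fits and "M8" in fits:
        lrts["M8_vs_M7"] = lrt(fits["M7"], fits["M8"])
    flagged: list[int] = []
    alpha = config.significance[0]
    for pair, alt in (("M2a_vs_M1a", "M2a"), ("M8_vs_M7", "M8")):
        r = lrts.get(pair)
        if r is not None and r.p_value < alpha and fits[alt].converged:
            sc = beb_classify(aln, tree, fits[alt])
            flagged = sorted(set(flagged) | set(sc.flagged_helix_positions()))
    return fits, lrts, flagged


def _apply_lengths(tree: Tree, cl: CodonLikelihood) -> None:
    nid = [0]

    def walk(node):
        this = nid[0]
        nid[0] += 1
        node.length = float(cl.index.lengths[this])
        for ch in node.children:
            walk(ch)

    walk(tree.root)
    tree.root.length = 0.0


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    records = list(config.records)
    for path in config.input_fasta:
        records += seq_io.read_fasta(path)
    if not records:
        raise ValueError("no input records")
    errors: list[str] = []
    status: dict[str, str] = {}

    # species resolution
    species_of: dict[str, str] = {}
    for rec in records:
        sp = _resolve_species(rec.id, config.species_map)
        if sp is None:
            errors.append(f"{rec.id}: species unresolvable")
        else:
            species_of[rec.id] = sp
    if len(species_of) < len(records):
        raise ValueError("unresolvable species for: " + ", ".join(errors))

    # paralog routing
    functional: list[SequenceRecord] = []
    disrupted: list[SequenceRecord] = []
    for rec in records:
        if config.refs:
            label, ident, _ = classify_paralog(rec, config.refs)
            (disrupted if "PRDM7" in label.upper() else functional).append(rec)
        else:
            rep = scan_orf(rec.seq, frame="auto", record_id=rec.id)
            (disrupted if rep.classification == "disrupted" else functional).append(rec)
    status["paralog_routing"] = f"{len(functional)} functional, {len(disrupted)} disrupted"

    # decomposition
    arrays: list[ZFArray] = []
    for rec in functional:
        try:
            arrays.append(
                segment_array(rec.seq, record_id=rec.id, species=species_of[rec.id])
            )
        except NotAZFArrayError as exc:
            errors.append(str(exc))
    status["decompose"] = f"{len(arrays)} arrays"

    # catalogue + genotypes
    catalog = build_catalog(arrays) if arrays else None
    genotypes = _genotypes_from_arrays(arrays)
    geno_df = genotype_summary(genotypes) if genotypes else None

    # disruption scan; repeat consensus from a same-species decomposed array
    reports = []
    consensus_by_species = {
        a.species: a.units[0].nt for a in reversed(arrays)
    }
    for rec in disrupted:
        rep = scan_orf(rec.seq, frame="auto", record_id=rec.id)
        cons = consensus_by_species.get(species_of[rec.id])
        if cons is not None:
            flags = detect_frameshift(rec.seq, cons, record_id=rec.id)
            rep.frameshift_flags = flags or []
        reports.append(rep)
    disruption = disruption_table(reports)
    status["scan"] = f"{len(reports)} records scanned"

    # selection per species and pooled
    user_tree = parse_newick(config.tree_newick) if config.tree_newick else None
    groups: dict[str, list[ZFArray]] = {"all": _dedupe_arrays(arrays)}
    for arr in arrays:
        groups.setdefault(arr.species, [])
    for sp in list(groups):
        if sp != "all":
            groups[sp] = _dedupe_arrays([a for a in arrays if a.species == sp])
    lrt_results: dict[str, dict] = {}
    beb_flagged: dict[str, list[int]] = {}
    all_fits: dict[str, dict] = {}
    for name in sorted(groups, key=lambda g: (g != "all", g)):
        group = groups[name]
        if len(group) < config.min_taxa:
            lrt_results[name] = {"M2a_vs_M1a": None, "M8_vs_M7": None}
            status[f"select:{name}"] = (
                f"insufficient data ({len(group)} distinct haplotypes)"
            )
            continue
        tree = None
        if user_tree is not None and name == "all":
            tree = user_tree.copy()
        try:
            fits, lrts, flagged = select_group(group, config, tree=tree)
        except ValueError as exc:
            errors.append(f"selection {name}: {exc}")
            lrt_results[name] = {"M2a_vs_M1a": None, "M8_vs_M7": None}
            status[f"select:{name}"] = f"failed: {exc}"
            continue
        lrt_results[name] = lrts
        beb_flagged[name] = flagged
        all_fits[name] = fits
        status[f"select:{name}"] = "ok"

    manifest = _manifest(config, records, status)
    result = PipelineResult(
        arrays=arrays, catalog=catalog, genotypes=geno_df, disruption=disruption,
        lrt_results=lrt_results, beb_flagged=beb_flagged, fits=all_fits,
        errors=errors, manifest=manifest,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _genotypes_from_arrays(arrays: list[ZFArray]) -> list[GenotypeRecord]:
    """Diploid genotypes for inputs named ``animal|h1|X`` / ``animal|h2|Y``."""
    by_animal: dict[str, list[ZFArray]] = {}
    for arr in arrays:
        if "|" in arr.record_id:
            by_animal.setdefault(arr.record_id.split("|")[0], []).append(arr)
    out = []
    for animal, arrs in sorted(by_animal.items()):
        if len(arrs) == 2:
            out.append(
                GenotypeRecord(animal, arrs[0].species,
                               (arrs[0].allele, arrs[1].allele))
            )
    return out


def _manifest(config: PipelineConfig, records, status) -> dict:
    cfg = asdict(config)
    cfg.pop("records", None)
    cfg.pop("out_dir", None)  # where outputs land must not change their hash
    cfg["refs"] = [r.id for r in config.refs]
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "tool": "zfselect 0.1.0",
        "config_hash": cfg_hash,
        "input_checksums": {
            r.id: hashlib.sha256(r.seq.encode()).hexdigest() for r in records
        },
        "stages": status,
    }


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save(df: pd.DataFrame | None, name: str) -> None:
        if df is None or df.empty:
            return
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    save(decomposition_table(result.arrays), "decomposition.tsv")
    if result.catalog is not None:
        save(result.catalog.to_frame(), "catalog.tsv")
        schem = pd.DataFrame(
            [
                {
                    "record_id": a.record_id,
                    "codes": ",".join(map(str, array_schematic(a, result.catalog)[0])),
                }
                for a in result.arrays
            ]
        )
        save(schem, "schematics.tsv")
    save(result.genotypes, "genotypes.tsv")
    save(result.disruption, "disruption.tsv")
    save(lrt_table(result.lrt_results), "lrt.tsv")
    bundle = {
        "beb_flagged_helix_positions": result.beb_flagged,
        "fits": {
            g: {
                m: {"lnL": f.lnL, "kappa": f.kappa,
                    "params": {k: float(v) for k, v in f.params.items()},
                    "converged": f.converged}
                for m, f in fits.items()
            }
            for g, fits in result.fits.items()
        },
        "errors": result.errors,
    }
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2))
    written["bundle.json"] = hashlib.sha256(
        (out / "bundle.json").read_bytes()
    ).hexdigest()
    result.manifest["outputs"] = written
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
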