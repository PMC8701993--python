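"""Stage orchestration: simulate -> blocks -> rates -> quartets -> detect -> stats -> enrich.

Each stage reads the previous stage's TSV artifacts from the output
directory, writes its own, and updates a machine-readable manifest with a
checksum per artifact, the configuration hash and the seed, so a rerun with
identical config and seed is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .colinearity import (BlockParams, KsEventWindows, date_blocks, detect_blocks,
                          filter_hits, read_blocks, write_blocks)
from .conversion import DetectorParams, calls_to_frame, detect_all, read_calls, summarize_calls
from .genome import read_gene_map, read_hits
from .genome_stats import (bin_by_terminal_distance, block_length_association,
                           chromosome_homogeneity, enrichment_chi2, enrichment_to_frame,
                           permutation_fold_test, terminal_fraction_table)
from .quartets import (QuartetFilterParams, attach_alignment, build_quartets,
                       filter_quartets, ortholog_map_from_blocks, paralog_pairs_from_blocks,
                       read_quartets, write_quartets)
from .rates import align_pair, ng86
from .simulate import SimConfig, simulate_genome_set

log = logging.getLogger(__name__)

STAGES = ["simulate", "blocks", "rates", "quartets", "detect", "stats", "enrich"]


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: Path = Path("quartetgc_out")
    genomes: list[dict] = field(default_factory=list)  # [{name, cds_fasta, gene_map}]
    hits_path: Path | None = None
    annotation_path: Path | None = None
    centromeres_path: Path | None = None
    block_params: BlockParams = field(default_factory=BlockParams)
    ks_windows: KsEventWindows = field(default_factory=KsEventWindows.default)
    quartet_filter: QuartetFilterParams = field(default_factory=QuartetFilterParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    sim: SimConfig | None = None
    dating_metric: str = "ps"  # "ps" | "ks_raw" (JC-corrected by default)
    bin_width_bp: int = 1_000_000
    first_k_bins: int = 1
    perm_rounds: int = 1_000_000
    rng_seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        paths = raw.get("paths", {})

        def p(key):
            v = paths.get(key)
            return None if v is None else (base / v)

        windows = raw.get("ks_windows")
        cfg = cls(
            outdir=base / paths.get("outdir", "quartetgc_out"),
            genomes=[{**g, "cds_fasta": base / g["cds_fasta"], "gene_map": base / g["gene_map"]}
                     for g in paths.get("genomes", [])],
            hits_path=p("hits"),
            annotation_path=p("annotation"),
            centromeres_path=p("centromeres"),
            block_params=BlockParams(**raw.get("block_params", {})),
            ks_windows=(KsEventWindows([(w["event"], w["lo"], w["hi"], w.get("hi_inclusive", False))
                                        for w in windows]) if windows else KsEventWindows.default()),
            quartet_filter=QuartetFilterParams(**raw.get("quartet_filter", {})),
            detector=DetectorParams(**raw.get("detector", {})),
            sim=SimConfig(**raw["simulate"]) if "simulate" in raw else None,
            dating_metric=raw.get("dating_metric", "ps"),
            bin_width_bp=int(raw.get("stats", {}).get("bin_width_bp", 1_000_000)),
            first_k_bins=int(raw.get("stats", {}).get("first_k_bins", 1)),
            perm_rounds=int(raw.get("stats", {}).get("perm_rounds", 1_000_000)),
            rng_seed=int(raw.get("rng_seed", 0)),
            raw=raw,
        )
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path | None, producing_stage: str, what: str) -> Path:
    if path is None or not Path(path).exists():
        raise StageError(
            f"missing {what} ({path}); run the '{producing_stage}' stage first")
    return Path(path)


class Pipeline:
    """Filesystem-backed runner for the pipeline stages."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- artifact paths ----------------------------------------------------
    def path(self, name: str) -> Path:
        return self.out / name

    def _manifest_update(self, stage: str, artifacts: list[Path]) -> None:
        mpath = self.path("manifest.json")
        manifest = {}
        if mpath.exists():
            manifest = json.loads(mpath.read_text())
        manifest.setdefault("run", {})
        manifest["run"] = {
            "tool": "quartetgc", "version": __version__,
            "seed": self.cfg.rng_seed, "config_hash": self.cfg.config_hash(),
        }
        manifest.setdefault("stages", {})
        manifest["stages"][stage] = {
            str(a.relative_to(self.out)): _sha256(a) for a in artifacts
        }
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    def _genome_inputs(self) -> list[dict]:
        if self.cfg.genomes:
            return self.cfg.genomes
        # default to the simulate stage's outputs
        simdir = self.path("sim")
        return [
            {"name": g, "cds_fasta": simdir / f"{g}.cds.fa", "gene_map": simdir / f"{g}.genes.gff3"}
            for g in ("G1", "G2")
        ]

    def _load_genomes(self):
        maps, cds = {}, {}
        for g in self._genome_inputs():
            name = g["name"]
            gm = _require(Path(g["gene_map"]), "simulate", f"gene map for {name}")
            fa = _require(Path(g["cds_fasta"]), "simulate", f"CDS FASTA for {name}")
            maps[name] = read_gene_map(gm, genome=name)
            cds.update({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fa), "fasta")})
        return maps, cds

    def _hits_path(self) -> Path:
        return Path(self.cfg.hits_path) if self.cfg.hits_path else self.path("sim/hits.tsv")

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        if self.cfg.sim is None:
            raise StageError("no 'simulate' section in the config")
        sim = dataclasses.replace(self.cfg.sim, rng_seed=self.cfg.rng_seed)
        rng = np.random.default_rng(sim.rng_seed)
        dataset = simulate_genome_set(sim, rng)
        paths = dataset.write(self.path("sim"))
        self._manifest_update("simulate", sorted(paths.values()))

    def stage_blocks(self) -> None:
        maps, _ = self._load_genomes()
        hits = read_hits(_require(self._hits_path(), "simulate", "homology hit table"))
        names = sorted(maps)
        blocks = []
        for i, a in enumerate(names):
            for b in names[i:]:
                ids_a = {g.gene_id for g in maps[a]}
                ids_b = {g.gene_id for g in maps[b]}
                sub = [h for h in hits
                       if (h.query_id in ids_a and h.subject_id in ids_b)
                       or (h.query_id in ids_b and h.subject_id in ids_a)]
                if a == b:
                    sub = [h for h in sub if h.query_id in ids_a and h.subject_id in ids_a]
                kept = filter_hits(sub, self.cfg.block_params)
                found = detect_blocks(maps[a], maps[b], kept, self.cfg.block_params)
                log.info("blocks %s-%s: %d hits -> %d kept -> %d blocks",
                         a, b, len(sub), len(kept), len(found))
                blocks.extend(found)
        write_blocks(blocks, self.path("blocks.tsv"), self.path("anchors.tsv"))
        self._manifest_update("blocks", [self.path("blocks.tsv"), self.path("anchors.tsv")])

    def stage_rates(self) -> None:
        _require(self.path("blocks.tsv"), "blocks", "block table")
        _, cds = self._load_genomes()
        blocks = read_blocks(self.path("blocks.tsv"), self.path("anchors.tsv"))
        pairs = sorted({tuple(sorted(a)) for b in blocks for a in b.anchors})
        rows = []
        for ga, gb in pairs:
            aln = align_pair(cds[ga], cds[gb], ids=(ga, gb))
            r = ng86(aln)
            rows.append([ga, gb, r.s_sites, r.n_sites, r.sd, r.nd, r.ks_raw, r.ka_raw,
                         r.ps, r.pn, r.pn_ps, ";".join(r.flags)])
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "s_sites", "n_sites", "sd", "nd",
                                         "ks_raw", "ka_raw", "ps", "pn", "pn_ps", "flags"])
        df.to_csv(self.path("pair_rates.tsv"), sep="\t", index=False)
        self._manifest_update("rates", [self.path("pair_rates.tsv")])

    def _pair_ks(self) -> dict[tuple[str, str], float]:
        df = pd.read_csv(_require(self.path("pair_rates.tsv"), "rates", "pair rates"), sep="\t")
        col = self.cfg.dating_metric
        return {(r.gene_a, r.gene_b): getattr(r, col) for r in df.itertuples()}

    def stage_quartets(self) -> None:
        maps, cds = self._load_genomes()
        blocks = read_blocks(_require(self.path("blocks.tsv"), "blocks", "block table"),
                             self.path("anchors.tsv"))
        dated = date_blocks(blocks, self._pair_ks(), self.cfg.ks_windows)
        write_blocks(dated, self.path("blocks_dated.tsv"), self.path("anchors_dated.tsv"))
        names = sorted(maps)
        focal, other = names[0], names[-1]
        intra = [b for b in dated if b.genome_a == focal and b.genome_b == focal]
        inter = [b for b in dated if {b.genome_a, b.genome_b} == {focal, other}]
        paralogs = paralog_pairs_from_blocks(intra, "LCT")
        omap = ortholog_map_from_blocks(inter, "PRT_or_speciation")
        quartets, n_same = build_quartets(paralogs, omap, omap, pattern="LCT")
        log.info("quartets: %d built, %d rejected (shared ortholog)", len(quartets), n_same)
        for q in quartets:
            attach_alignment(q, cds)
        filtered = filter_quartets(quartets, self.cfg.quartet_filter)
        log.info("quartet filter: kept=%d removed_gap=%d removed_identity=%d",
                 *(len(filtered[k]) for k in ("kept", "removed_gap", "removed_identity")))
        write_quartets(quartets, self.path("quartets.tsv"), self.path("alignments"))
        arts = [self.path("blocks_dated.tsv"), self.path("anchors_dated.tsv"),
                self.path("quartets.tsv")]
        arts += sorted(self.path("alignments").glob("*.aln.fa"))
        self._manifest_update("quartets", arts)

    def stage_detect(self) -> None:
        quartets = read_quartets(
            _require(self.path("quartets.tsv"), "quartets", "quartet table"),
            self.path("alignments"))
        res = detect_all(quartets, self.cfg.detector, seed=self.cfg.rng_seed)
        calls_to_frame(res.calls).to_csv(self.path("calls.tsv"), sep="\t", index=False)
        summarize_calls(quartets, res.calls).to_csv(self.path("summary.tsv"), sep="\t", index=False)
        self._manifest_update("detect", [self.path("calls.tsv"), self.path("summary.tsv")])

    def _gene_sets(self):
        quartets = read_quartets(_require(self.path("quartets.tsv"), "quartets", "quartet table"))
        calls = read_calls(_require(self.path("calls.tsv"), "detect", "call table"))
        kept = [q for q in quartets if q.filter_status == "kept"]
        called = {c.quartet_id for c in calls}
        duplicated = {g for q in kept for g in q.genes[:2]}
        converted = {g for q in kept if q.quartet_id in called for g in q.genes[:2]}
        return quartets, calls, duplicated, converted

    def stage_stats(self) -> None:
        maps, _ = self._load_genomes()
        focal = sorted(maps)[0]
        quartets, calls, duplicated, converted = self._gene_sets()
        centromeres = None
        if self.cfg.centromeres_path:
            cdf = pd.read_csv(self.cfg.centromeres_path, sep="\t")
            centromeres = dict(zip(cdf.chromosome, cdf.position))
        series = bin_by_terminal_distance(
            maps[focal], duplicated, converted,
            arm_boundaries=centromeres, bin_width_bp=self.cfg.bin_width_bp,
            first_k_bins=self.cfg.first_k_bins)
        artifacts = []
        if series.occupied.sum() >= 2:
            series = permutation_fold_test(series, rounds=self.cfg.perm_rounds,
                                           seed=self.cfg.rng_seed)
        bins_df = series.to_frame()
        bins_df.to_csv(self.path("bins.tsv"), sep="\t", index=False)
        pd.DataFrame([{
            "fold_increase": series.fold_increase, "perm_p": series.perm_p,
            "perm_rounds": series.perm_rounds, "approx_arms": series.approx_arms,
        }]).to_csv(self.path("fold_test.tsv"), sep="\t", index=False)
        artifacts += [self.path("bins.tsv"), self.path("fold_test.tsv")]
        try:
            chi2, p, per_chrom = chromosome_homogeneity(maps[focal], duplicated, converted)
            per_chrom.to_csv(self.path("per_chromosome.tsv"), sep="\t", index=False)
            pd.DataFrame([{"chi2": chi2, "p": p}]).to_csv(
                self.path("chromosome_homogeneity.tsv"), sep="\t", index=False)
            artifacts += [self.path("per_chromosome.tsv"), self.path("chromosome_homogeneity.tsv")]
        except ValueError as e:
            log.warning("chromosome homogeneity skipped: %s", e)
        blocks = read_blocks(self.path("blocks_dated.tsv"), self.path("anchors_dated.tsv"))
        intra = [b for b in blocks if b.genome_a == focal and b.genome_b == focal
                 and b.event == "LCT"]
        table, r2 = block_length_association(intra, converted)
        table.to_csv(self.path("block_classes.tsv"), sep="\t", index=False)
        pd.DataFrame([{"r_squared": r2}]).to_csv(self.path("block_assoc.tsv"), sep="\t", index=False)
        terminal_fraction_table(maps[focal], converted).to_csv(
            self.path("terminal_fractions.tsv"), sep="\t", index=False)
        artifacts += [self.path("block_classes.tsv"), self.path("block_assoc.tsv"),
                      self.path("terminal_fractions.tsv")]
        self._manifest_update("stats", artifacts)

    def stage_enrich(self) -> None:
        ann_path = self.cfg.annotation_path or self.path("sim/annotation.tsv")
        ann = pd.read_csv(_require(ann_path, "simulate", "annotation table"), sep="\t")
        _, _, duplicated, converted = self._gene_sets()
        rows = enrichment_chi2(ann, converted, duplicated)
        enrichment_to_frame(rows).to_csv(self.path("enrichment.tsv"), sep="\t", index=False)
        self._manifest_update("enrich", [self.path("enrichment.tsv")])

    def run(self, stage: str) -> None:
        if stage == "all":
            order = STAGES if self.cfg.sim is not None else STAGES[1:]
            for s in order:
                if s == "enrich" and self.cfg.annotation_path is None and self.cfg.sim is None:
                    continue
                self.run(s)
            return
        if stage not in STAGES:
            raise StageError(f"unknown stage {stage!r}; choose from {STAGES + ['all']}")
        log.info("running stage %s", stage)
        getattr(self, f"stage_{stage}")()


def run_stage(stage: str, cfg: RunConfig) -> Path:
    """Run one stage (or 'all'); returns the output directory."""
    Pipeline(cfg).run(stage)
    return Path(cfg.outdir)
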