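"""End-to-end orchestration: simulate → metagene → callorfs → count/TE →
builddb → quant, driven by a single flat key-value (YAML) config.

Every stochastic stage draws its seed deterministically from the master seed
(stable CRC32 hashing of "seed:stage"), so a rerun with an identical config
reproduces byte-identical outputs; a manifest records parameters, output
checksums and drop/warning counters.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import genome as gm
from . import immuno, orfs, peptidedb, profiles, quant
from . import simulate as sim

log = logging.getLogger("riboshift")

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    """Flat pipeline configuration; every stochastic stage needs a seed."""

    seed: Optional[int] = None
    outdir: str = "riboshift_out"
    # simulation
    n_genes: int = 50
    library_size: int = 50_000
    n_replicates: int = 3
    front_load_ratio: float = 2.0
    uorf_occupancy: float = 0.03
    periodicity: float = 0.9
    # metagene / occupancy
    smoothing_sigma: float = 5.0
    min_reads: int = 50
    # ORF calling
    min_psites: int = 10
    pmax: float = 0.05
    start_codons: list = field(default_factory=lambda: list(orfs.DEFAULT_START_CODONS))
    # counting / TE
    min_feature_reads: int = 5
    # immunopeptide quant
    n_peptides: int = 500
    n_per_group: int = 3
    planted_fraction: float = 0.05
    planted_log2fc: float = 2.0
    missing_rate: float = 0.05
    fc_hit: float = 2.0
    fdr_hit: float = 0.05
    fc_cand: float = 1.5
    fdr_cand: float = 0.2

    _RANGES = {
        "smoothing_sigma": (0.0, 100.0),
        "periodicity": (0.0, 1.0),
        "uorf_occupancy": (0.0, 1.0),
        "missing_rate": (0.0, 0.999),
        "planted_fraction": (0.0, 1.0),
        "pmax": (0.0, 1.0),
        "front_load_ratio": (1e-9, 1e9),
    }

    def problems(self) -> list[str]:
        out = []
        if self.seed is None:
            out.append("missing seed: every stochastic stage requires an explicit seed")
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                out.append(f"{name}={v} out of range [{lo}, {hi}]")
        for name in ("n_genes", "library_size", "n_replicates", "n_peptides",
                     "n_per_group", "min_reads", "min_psites", "min_feature_reads"):
            if getattr(self, name) <= 0:
                out.append(f"{name} must be positive")
        return out


def load_config(path: str | Path) -> tuple[RunConfig, list[str]]:
    """Parse a YAML config; returns (config, problems incl. unknown keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    problems = []
    clean = {}
    for key, value in raw.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            problems.append(f"unknown key {key!r}{suffix}")
        else:
            clean[key] = value
    cfg = RunConfig(**clean)
    problems.extend(cfg.problems())
    return cfg, problems


def validate_config(path: str | Path) -> list[str]:
    """Config validation report; empty list means clean."""
    _, problems = load_config(path)
    return problems


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (< 2^31)."""
    return zlib.crc32(f"{master}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(cfg: RunConfig) -> sim.SimConfig:
    return sim.SimConfig(
        n_genes=cfg.n_genes,
        library_size=cfg.library_size,
        front_load_ratio=cfg.front_load_ratio,
        uorf_occupancy=cfg.uorf_occupancy,
        periodicity=cfg.periodicity,
        seed=cfg.seed,
    )


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    Outputs land under ``config.outdir``; the manifest (written there as
    ``manifest.json``) records the parameter hash, per-file sha256 checksums
    and per-stage counters, and is reproducible for identical configs.
    """
    if not isinstance(config, RunConfig):
        config, problems = load_config(config)
    else:
        problems = config.problems()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counters: dict[str, dict] = {}
    outputs: list[Path] = []

    # ---- stage 1: simulate -------------------------------------------------
    sc = _sim_config(config)
    txome = sim.simulate_transcriptome(sc, seed=stage_seed(config.seed, "transcriptome"))
    txome.write_genome_fasta(out / "genome.fa")
    txome.write_gtf(out / "annotation.gtf")
    txome.write_truth(out / "planted_orfs.tsv")
    outputs += [out / "genome.fa", out / "annotation.gtf", out / "planted_orfs.tsv"]

    libs: dict[str, pd.DataFrame] = {}
    for regime in ("proliferating", "arrested"):
        for rep in range(1, config.n_replicates + 1):
            name = f"{regime}_{rep}"
            fps = sim.simulate_footprints(
                txome, regime, sc, seed=stage_seed(config.seed, f"fp:{name}")
            )
            libs[name] = fps
            path = out / f"footprints_{name}.bed"
            sim.write_footprint_bed(fps, path)
            outputs.append(path)
    counters["simulate"] = {
        "n_transcripts": len(txome.models),
        "n_planted_orfs": int(len(txome.truth)),
        "n_libraries": len(libs),
    }
    log.info("simulate: %s", counters["simulate"])

    # ---- stage 2: metagene + redistribution --------------------------------
    tracks = {
        name: profiles.tracks_from_footprints(fps, txome.models) for name, fps in libs.items()
    }
    occ = {
        name: [
            profiles.region_occupancy(tr, txome.models[tid], config.min_reads)
            for tid, tr in sorted(trs.items())
        ]
        for name, trs in tracks.items()
    }
    prolif = [occ[f"proliferating_{r}"] for r in range(1, config.n_replicates + 1)]
    arrest = [occ[f"arrested_{r}"] for r in range(1, config.n_replicates + 1)]
    can_test = config.n_replicates >= 2
    ratio = profiles.utr_ratio_statistic(prolif, arrest, test=can_test)
    mg = profiles.metagene_profile(
        tracks["arrested_1"], txome.models, config.smoothing_sigma, config.min_reads
    )
    mg.to_frame().to_csv(out / "metagene_arrested.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "replicate": [f"prolif_{i+1}" for i in range(config.n_replicates)]
            + [f"arrest_{i+1}" for i in range(config.n_replicates)],
            "frac_5utr": np.concatenate([ratio.frac5_a, ratio.frac5_b]),
            "frac_3utr": np.concatenate([ratio.frac3_a, ratio.frac3_b]),
        }
    ).to_csv(out / "utr_fractions.tsv", sep="\t", index=False)
    with open(out / "utr_ratio.json", "w") as fh:
        json.dump(
            {
                "ratio_arrested_vs_proliferating": ratio.ratio_b_over_a,
                "t_stat": ratio.t_stat,
                "p_value": ratio.p_value,
            },
            fh,
            indent=2,
        )
    outputs += [out / "metagene_arrested.tsv", out / "utr_fractions.tsv", out / "utr_ratio.json"]
    counters["metagene"] = {"n_transcripts_used": mg.n_transcripts_used}

    # ---- stage 3: ORF calling on pooled arrested libraries -----------------
    pooled = pd.concat(
        [libs[f"arrested_{r}"] for r in range(1, config.n_replicates + 1)],
        ignore_index=True,
    )
    pooled_tracks = profiles.tracks_from_footprints(pooled, txome.models)
    orf_tables = []
    for tid in sorted(pooled_tracks):
        orf_tables.append(
            orfs.call_orfs(
                txome.models[tid],
                txome.tx_seq[tid],
                pooled_tracks[tid],
                config.start_codons,
                config.min_psites,
            )
        )
    orf_table = pd.concat(orf_tables, ignore_index=True)
    orf_table.to_csv(out / "orfs_all.tsv", sep="\t", index=False)
    called = orf_table[orf_table.p_value <= config.pmax].reset_index(drop=True)
    called.to_csv(out / "orfs_called.tsv", sep="\t", index=False)
    outputs += [out / "orfs_all.tsv", out / "orfs_called.tsv"]
    counters["callorfs"] = {
        "n_candidates": int(len(orf_table)),
        "n_called": int(len(called)),
        "by_category": called.category.value_counts().to_dict(),
    }

    # ---- stage 4: counting + TE on upstream ORFs ---------------------------
    upstream = called[called.category.isin(["uORF", "uoORF"])].reset_index(drop=True)
    saf = pd.DataFrame(
        {
            "GeneID": [f"{r.transcript_id}:{r.start}-{r.end}" for r in upstream.itertuples()],
            "Chr": upstream.transcript_id,
            "Start": upstream.start + 1,
            "End": upstream.end,
            "Strand": "+",
        }
    )
    saf.to_csv(out / "uorfs.saf", sep="\t", index=False)
    outputs.append(out / "uorfs.saf")
    te_path = out / "te_results.tsv"
    if len(saf):
        psites = {}
        for regime in ("proliferating", "arrested"):
            frames = []
            for r in range(1, config.n_replicates + 1):
                trs = tracks[f"{regime}_{r}"]
                for tid, tr in trs.items():
                    pos = np.repeat(np.arange(len(tr.counts)), tr.counts)
                    frames.append(pd.DataFrame({"chrom": tid, "pos": pos}))
            psites[regime] = pd.concat(frames, ignore_index=True)
        cm = quant.count_features(psites, saf)
        cm = quant.filter_min_reads(cm, config.min_feature_reads)
        rna = sim.simulate_rnaseq_counts(
            txome,
            sc,
            features=pd.DataFrame(
                {
                    "feature_id": saf.GeneID,
                    "transcript_id": saf.Chr,
                    "start": saf.Start - 1,
                    "end": saf.End,
                }
            ),
            n_samples=2,
            seed=stage_seed(config.seed, "rnaseq"),
        ).set_index("feature_id")
        rna = rna.loc[cm.feature_ids]
        ribo = cm.to_frame()
        te = quant.delta_te(
            ribo["proliferating"].to_numpy(),
            rna["sample_1"].to_numpy(),
            ribo["arrested"].to_numpy(),
            rna["sample_2"].to_numpy(),
            ribo["proliferating"].sum(),
            rna["sample_1"].sum(),
            ribo["arrested"].sum(),
            rna["sample_2"].sum(),
            feature_ids=cm.feature_ids,
        )
        te.to_csv(te_path, sep="\t", index=False)
        counters["te"] = {
            "n_features": int(len(te)),
            "n_tested": int((te.status == "tested").sum()),
        }
    else:
        pd.DataFrame().to_csv(te_path, sep="\t")
        counters["te"] = {"n_features": 0, "n_tested": 0}
    outputs.append(te_path)

    # ---- stage 5: peptide database -----------------------------------------
    proteome = [
        (
            f"{txome.models[tid].gene_id}|{tid}|proteome",
            peptidedb.translate_orf(
                txome.tx_seq[tid][txome.models[tid].cds_tx[0] : txome.models[tid].cds_tx[1]]
            ),
        )
        for tid in sorted(txome.models)
    ]
    bed12 = peptidedb.orfs_to_bed12(upstream, txome.models, pmax=None)
    peptidedb.write_bed12(bed12, out / "uorfs.bed12")
    records, db_stats = peptidedb.build_database(
        upstream, txome.models, txome.genome, proteome, pmax=None,
        tx_sequences=txome.tx_seq,
    )
    peptidedb.write_fasta(records, out / "search_database.fa")
    outputs += [out / "uorfs.bed12", out / "search_database.fa"]
    counters["builddb"] = db_stats

    # ---- stage 6: immunopeptide quantification -----------------------------
    n_planted = int(round(config.planted_fraction * config.n_peptides))
    planted = np.zeros(config.n_peptides)
    planted[:n_planted] = config.planted_log2fc
    mat, truth = sim.simulate_intensity_matrix(
        config.n_peptides,
        config.n_per_group,
        planted,
        config.missing_rate,
        seed=stage_seed(config.seed, "intensity"),
    )
    mat.to_csv(out / "intensities.tsv", sep="\t")
    truth.to_csv(out / "intensity_truth.tsv", sep="\t", index=False)
    res = immuno.differential_peptides(
        mat,
        ["A"] * config.n_per_group + ["B"] * config.n_per_group,
        config.fc_hit, config.fdr_hit, config.fc_cand, config.fdr_cand,
    )
    res.table.to_csv(out / "differential_peptides.tsv", sep="\t")
    outputs += [out / "intensities.tsv", out / "intensity_truth.tsv", out / "differential_peptides.tsv"]
    counters["quant"] = {
        "prior_df": res.prior_df if np.isfinite(res.prior_df) else "inf",
        "classes": res.table["class"].value_counts().to_dict(),
    }

    # ---- manifest ----------------------------------------------------------
    params = asdict(config)
    hashed = {k: v for k, v in params.items() if k != "outdir"}  # location-free
    manifest = {
        "parameters": params,
        "parameter_hash": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in outputs},
        "counters": counters,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
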