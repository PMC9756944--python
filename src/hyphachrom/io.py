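"""Shared readers/writers, run configuration and the end-to-end pipeline.

All artifacts are plain text (CSV/TSV, BED6, FASTA, JSON) so a complete
run is diffable and reproducible from a single seed.  ``run_pipeline``
executes the synthetic-data generators and every analysis stage in
dependency order and writes a machine-readable manifest with the
parameters, seed and SHA-256 content hashes of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "RunConfig",
    "run_pipeline",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a validated, sorted interval frame.

    Coordinates are 0-based half-open; strand is preserved when present.
    Malformed lines are reported with their line numbers.
    """
    rows = []
    errors = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                errors.append(f"line {ln}: fewer than 3 fields")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                errors.append(f"line {ln}: non-integer coordinates")
                continue
            if start < 0 or start >= end:
                errors.append(f"line {ln}: invalid interval [{start}, {end})")
                continue
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    if errors:
        raise ValueError("malformed BED: " + "; ".join(errors))
    df = pd.DataFrame(rows, columns=_BED_COLS)
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: sequence} (case preserved).

    Raises on duplicate headers; an empty file gives an empty dict.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Umbrella configuration; defaults follow the analysis conventions
    used throughout the package (0.6 um / 1-gap / 30 ms tracking, 3-step
    mobility window, 69/23/2000/2/100/0.05 windowed binding, 200 bp
    coverage bins, 10-min imaging, 16 h / 60 min / 120 min phenotype
    rules)."""

    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "INFO"
    spt_sim: dict = field(default_factory=dict)
    hypha_sim: dict = field(default_factory=dict)
    chip_sim: dict = field(default_factory=dict)
    growth_sim: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    mixture: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    phenotype: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run simulation and all four analysis stages; return the run directory.

    Stages run in dependency order; every stage writes its outputs
    before the next starts, so a failure leaves earlier artifacts
    intact.  A ``manifest.json`` records parameters, the seed and the
    SHA-256 hash of every artifact; reruns with the same config are
    bit-identical.
    """
    from . import chip as C
    from . import growth as G
    from . import hyphal as H
    from . import simulate as S
    from . import spt as T

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    artifacts: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw) -> Path:
        p = out / name
        df.to_csv(p, sep="\t", index=False, **kw)
        artifacts.append(p)
        return p

    # --- simulate ---------------------------------------------------------
    spt_cfg = S.SPTSimConfig(**{"seed": seed, **config.spt_sim})
    locs, spt_truth = S.simulate_spt(spt_cfg)
    save(locs, "spt_localizations.tsv")
    save(spt_truth, "spt_truth.tsv")

    hy_cfg = S.HyphaSimConfig(**{"seed": seed + 1, **config.hypha_sim})
    hyphae, profiles, foci_truth, events = S.simulate_hyphae(hy_cfg)
    save(hyphae, "hyphae.tsv")
    save(profiles, "profiles.tsv")
    save(foci_truth, "foci_truth.tsv")
    save(events, "events_truth.tsv")

    chip_cfg = S.ChIPSimConfig(**{"seed": seed + 2, **config.chip_sim})
    fragments, genome, chip_truth = S.simulate_chip(chip_cfg)
    write_fasta({"chr": genome}, out / "genome.fasta")
    artifacts.append(out / "genome.fasta")
    for name, df in fragments.items():
        write_bed(df, out / f"fragments_{name}.bed")
        artifacts.append(out / f"fragments_{name}.bed")
    save(chip_truth, "chip_truth.tsv")

    growth_cfg = S.GrowthSimConfig(**{"seed": seed + 3, **config.growth_sim})
    od = S.simulate_growth(growth_cfg)
    p = out / "growth_od.csv"
    od.to_csv(p, index=False)
    artifacts.append(p)

    # --- spt analysis -----------------------------------------------------
    tcfg = T.TrackingConfig(**config.tracking)
    tracks = T.link_tracks(locs, tcfg)
    save(T.tracks_to_frame(tracks), "tracks.tsv")
    mix_kw = {"dt": tcfg.dt, "loc_sigma": spt_cfg.loc_sigma, **config.mixture}
    fit = T.fit_diffusion_mixture(tracks, **mix_kw)
    classes = T.classify_mobility(tracks, fit)
    save(classes, "mobility.tsv")
    fit_json = {
        "D_app_um2_s": fit.D_app.tolist(),
        "weights": fit.weights.tolist(),
        "log_likelihood": fit.log_likelihood,
        "mean_D_app_um2_s": fit.mean_D_app,
        "n_steps": fit.n_steps,
        "mobility_fractions": T.mobility_fractions(classes),
    }
    (out / "diffusion_fit.json").write_text(json.dumps(fit_json, indent=2))
    artifacts.append(out / "diffusion_fit.json")

    # --- hyphal analysis --------------------------------------------------
    pk = H.PeakDetectConfig(**{"pixel_size": hy_cfg.pixel_size, **config.peaks})
    foci = H.detect_foci_all(profiles, pk)
    save(foci, "foci.tsv")
    rules = H.PhenotypeRules(**config.phenotype)
    pheno_rows = []
    for hid, g in hyphae.groupby("hypha_id"):
        kind = "branch" if g["parent_id"].notna().any() else "spore"
        pheno_rows.append((hid, kind, H.classify_phenotype(g, rules, kind=kind)))
    save(pd.DataFrame(pheno_rows, columns=["hypha_id", "kind", "phenotype"]), "phenotypes.tsv")
    all_events = []
    for hid, g in foci.groupby("hypha_id"):
        _, evs = H.track_foci(g, frame_interval=hy_cfg.frame_interval)
        all_events.extend(evs)
    M, means = H.duplication_heatmap(all_events)
    save(pd.DataFrame(M), "duplication_heatmap.tsv")

    # --- chip analysis ----------------------------------------------------
    wcfg = C.WindowConfig(**config.windows)
    windows = C.tile_windows(chip_cfg.genome_length, wcfg)
    counted = C.count_fragments(windows, fragments, wcfg)
    filtered = C.local_filter(counted, fragments, chip_cfg.genome_length, wcfg)
    samples = list(fragments)
    groups = np.array([s.rsplit("_rep", 1)[0] for s in samples])
    libs = np.array([len(fragments[s]) for s in samples], dtype=float)
    tested = filtered[filtered["retained"]].reset_index(drop=True)
    if len(tested) >= 2:
        phi = C.estimate_dispersion(tested[samples].to_numpy(), groups, libs)
        res = C.nb_test(tested[samples].to_numpy(), groups, phi, libs)
        tested = pd.concat([tested[["start", "end"]], res], axis=1)
        sig_windows = tested
        regions = C.merge_and_combine(sig_windows, wcfg)
        regions["at_fraction"] = [
            C.at_fraction(genome, int(s), int(e)) for s, e in zip(regions["start"], regions["end"])
        ]
    else:
        regions = C.merge_and_combine(pd.DataFrame(columns=["start", "end", "p"]), wcfg)
    save(regions, "regions.tsv")
    cov = C.binned_coverage(fragments, chip_cfg.genome_length, C.CoverageConfig(**config.coverage))
    save(cov, "coverage.tsv")

    # --- growth analysis --------------------------------------------------
    reps = [c for c in od.columns if c != "time_h"]
    t_all = np.tile(od["time_h"].to_numpy(), len(reps))
    od_all = np.concatenate([od[c].to_numpy() for c in reps])
    gfit = G.fit_log_logistic(t_all, od_all)
    (out / "growth_fit.json").write_text(json.dumps(dataclasses.asdict(gfit), indent=2))
    artifacts.append(out / "growth_fit.json")

    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
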