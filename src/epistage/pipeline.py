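"""End-to-end orchestration: QC -> pairwise screening -> K-locus search.

The pipeline report carries every detected K-SNP set with its statistic,
degrees of freedom, p-value and the Bonferroni level it beat, together
with the effective configuration and a log of the screening-band sizes
(the candidate count W drives the stage-2 strategy choice).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .genotype_data import GenotypeDataset, QcThresholds, load_dataset, quality_control
from .screening import ScreenResult, screen
from .search import AcoConfig, Stage2Result, run_stage2

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "write_report",
           "read_report", "make_detector"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    input: str | None = None
    format: str = "tsv"
    dataset: GenotypeDataset | None = None   # bypasses file loading
    alpha0: float = 0.05
    omega: float = 1e4
    order: int = 3
    strategy: str = "auto"
    aco: AcoConfig | None = None
    seed: int | None = None
    qc: bool = True
    qc_thresholds: QcThresholds | None = None

    def __post_init__(self) -> None:
        if self.order < 3:
            raise ValueError("interaction order must be >= 3")
        if self.input is None and self.dataset is None:
            raise ValueError("either an input path or an in-memory dataset is required")

    def as_dict(self) -> dict:
        aco = self.aco if self.aco is not None else AcoConfig(seed=self.seed)
        return {
            "input": self.input, "format": self.format, "alpha0": self.alpha0,
            "omega": self.omega, "order": self.order, "strategy": self.strategy,
            "seed": self.seed, "qc": self.qc,
            "aco": {k: getattr(aco, k) for k in
                    ("tau0", "n_ants", "rho", "d", "max_iter", "delta", "beta",
                     "eta", "fs", "top_t", "seed")},
        }


@dataclass
class PipelineReport:
    rows: list[dict]
    config: dict
    log: list[str] = field(default_factory=list)
    qc_report: object = None  # pandas DataFrame (entity, kind, rule, value, threshold)

    @property
    def interactions(self) -> list[tuple[tuple[str, ...], float, float]]:
        return [(tuple(r["snps"]), r["chi2"], r["p_value"]) for r in self.rows]


def run_pipeline(cfg: RunConfig) -> PipelineReport:
    """QC -> screen -> stage-2 search -> report."""
    log: list[str] = []
    ds = cfg.dataset if cfg.dataset is not None else load_dataset(cfg.input, cfg.format)
    log.append(f"loaded {ds.n_samples} samples ({ds.n_cases} cases, "
               f"{ds.n_controls} controls), {ds.n_snps} SNPs")
    qc_report = None
    if cfg.qc:
        ds, qc_report = quality_control(ds, cfg.qc_thresholds)
        log.append(f"QC removed {len(qc_report)} entities; {ds.n_snps} SNPs remain")

    sres: ScreenResult = screen(ds, alpha0=cfg.alpha0, omega=cfg.omega)
    log.append(f"screening: {sres.n_pairs_scanned} pairs scanned, "
               f"{sres.n_significant} significant, {sres.n_intermediate} intermediate, "
               f"{len(sres.flagged)} SNPs flagged for strong main effects, "
               f"{sres.n_lrt_discarded}/{sres.n_lrt_tested} pairs discarded by the LRT")
    log.append(f"candidate pairs W = {len(sres.candidates)}")

    if not sres.candidates:
        log.append("no candidate pairs survive screening: empty report")
        return PipelineReport(rows=[], config=cfg.as_dict(), log=log,
                              qc_report=qc_report)

    aco = cfg.aco if cfg.aco is not None else AcoConfig(seed=cfg.seed)
    if aco.seed is None and cfg.seed is not None:
        from dataclasses import replace
        aco = replace(aco, seed=cfg.seed)
    stage2: Stage2Result = run_stage2(
        sres.candidates, ds, K=cfg.order, config=aco,
        alpha0=cfg.alpha0, M=ds.n_snps, strategy=cfg.strategy,
    )
    log.append(f"stage 2 used the {stage2.strategy} strategy; "
               f"{len(stage2.interactions)} significant {cfg.order}-SNP sets")

    rows = [
        {
            "snps": tuple(ds.snp_ids[i] for i in snps),
            "snp_indices": snps,
            "chi2": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "bonferroni_level": stage2.bonferroni_level,
            "strategy": stage2.strategy,
        }
        for snps, res in stage2.interactions
    ]
    return PipelineReport(rows=rows, config=cfg.as_dict(), log=log,
                          qc_report=qc_report)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def write_report(report: PipelineReport, path: str, order: int | None = None) -> None:
    """Serialize a report as TSV with version/config header comments."""
    if order is None:
        order = max((len(r["snps"]) for r in report.rows), default=report.config.get("order", 3))
    cols = [f"snp_{i + 1}" for i in range(order)] + [
        "chi2", "df", "p_value", "bonferroni_level", "strategy"]
    with open(path, "w") as fh:
        fh.write(f"# epistage {VERSION}\n")
        fh.write(f"# config_hash {_config_hash(report.config)}\n")
        fh.write(f"# config {json.dumps(report.config, sort_keys=True)}\n")
        fh.write("\t".join(cols) + "\n")
        for r in report.rows:
            cells = list(r["snps"]) + [
                f"{r['chi2']:.6f}", str(r["df"]), f"{r['p_value']:.6e}",
                f"{r['bonferroni_level']:.6e}", r["strategy"]]
            fh.write("\t".join(cells) + "\n")


def read_report(path: str) -> tuple[list[dict], dict]:
    """Round-trip reader for :func:`write_report` output."""
    rows: list[dict] = []
    meta: dict = {}
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# config "):
                meta = json.loads(line[len("# config "):])
                continue
            if line.startswith("#") or not line:
                continue
            if header is None:
                header = line.split("\t")
                continue
            cells = line.split("\t")
            k = len(header) - 5
            rows.append({
                "snps": tuple(cells[:k]),
                "chi2": float(cells[k]),
                "df": int(cells[k + 1]),
                "p_value": float(cells[k + 2]),
                "bonferroni_level": float(cells[k + 3]),
                "strategy": cells[k + 4],
            })
    return rows, meta


def make_detector(
    alpha0: float = 0.05,
    omega: float = 1e4,
    order: int = 3,
    strategy: str = "auto",
    aco: AcoConfig | None = None,
):
    """Detector callable for power estimation: dataset -> reported SNP
    index tuples.  QC is skipped so column indices stay aligned with the
    simulator's truth record."""

    def detect(ds: GenotypeDataset) -> list[tuple[int, ...]]:
        cfg = RunConfig(dataset=ds, alpha0=alpha0, omega=omega, order=order,
                        strategy=strategy, aco=aco, qc=False)
        report = run_pipeline(cfg)
        return [tuple(r["snp_indices"]) for r in report.rows]

    return detect
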