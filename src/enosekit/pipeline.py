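"""Config-driven end-to-end run.

``run_pipeline`` chains simulate -> repeatability -> feature extraction
-> PCA -> LDA -> classifier benchmark and writes every artifact
(traces.csv + manifest, features.csv, rsd.json, pca.json, lda.json,
benchmark.json, run.log) into one output directory.  A single global
seed fans out to per-stage seeds by stable hashing of the stage name,
so each stage is independently reproducible; outputs are staged in a
temporary directory and renamed into place only on success, so a
failed run leaves nothing behind.
"""

from __future__ import annotations

import logging
import shutil
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .chemometrics import LDA_PROTOCOLS, compute_rsd, lda_fit, pca_fit
from .classification import ALGORITHMS, SplitSpec, run_benchmark
from .features import FEATURE_CODES, FeatureConfig, extract_features
from .io import dump_json, write_feature_matrix, write_traces
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "ChemometricsConfig", "ClassificationConfig",
           "derive_seed", "run_pipeline"]

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "traces.csv", "features.csv", "rsd.json", "pca.json", "lda.json", "benchmark.json",
)


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed from the global seed (stable across runs and platforms)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class ChemometricsConfig:
    pca_components: int = 2
    lda_protocol: str = "resubstitution"
    rsd_grade: int = 1

    def __post_init__(self) -> None:
        if self.pca_components < 1:
            raise ValueError("pca_components must be positive")
        if self.lda_protocol not in LDA_PROTOCOLS:
            raise ValueError(
                f"unknown LDA protocol {self.lda_protocol!r}; choose from {LDA_PROTOCOLS}"
            )
        if self.rsd_grade < 1:
            raise ValueError("rsd_grade must be a valid grade label")


@dataclass
class ClassificationConfig:
    train_per_class: int = 21
    codes: tuple[str, ...] = FEATURE_CODES
    algorithms: tuple[str, ...] = ALGORITHMS

    def __post_init__(self) -> None:
        if self.train_per_class < 1:
            raise ValueError("train_per_class must be positive")
        unknown = set(self.codes) - set(FEATURE_CODES)
        if unknown:
            raise ValueError(f"unknown feature codes: {sorted(unknown)}")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        self.codes = tuple(self.codes)
        self.algorithms = tuple(self.algorithms)


_SECTIONS = {
    "synthetic": SyntheticConfig,
    "features": FeatureConfig,
    "chemometrics": ChemometricsConfig,
    "classification": ClassificationConfig,
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "enose-run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    chemometrics: ChemometricsConfig = field(default_factory=ChemometricsConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - ({"outdir", "seed"} | set(_SECTIONS))
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs: dict = {
            "outdir": data.get("outdir", "enose-run"),
            "seed": int(data.get("seed", 0)),
        }
        for name, section_cls in _SECTIONS.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            if name == "synthetic":
                kwargs[name] = SyntheticConfig.from_dict(section)
            else:
                known = set(section_cls.__dataclass_fields__)
                bad = set(section) - known
                if bad:
                    raise ValueError(f"unknown keys in section {name!r}: {sorted(bad)}")
                if name == "features" and "wavelet" in section:
                    from .features import WaveletSpec

                    section = dict(section)
                    section["wavelet"] = WaveletSpec(**section["wavelet"])
                kwargs[name] = section_cls(**section)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": int(self.seed),
            "synthetic": self.synthetic.to_dict(),
            "features": {
                "smooth": self.features.smooth,
                "baseline": self.features.baseline,
                "t0": self.features.t0,
                "wavelet": asdict(self.features.wavelet),
            },
            "chemometrics": asdict(self.chemometrics),
            "classification": asdict(self.classification),
        }


def run_pipeline(config: RunConfig, overwrite: bool = False) -> Path:
    """Execute every stage and return the populated run directory."""
    outdir = Path(config.outdir)
    if outdir.exists() and not overwrite:
        raise FileExistsError(f"output directory {outdir} already exists")
    tmp = outdir.with_name(outdir.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)

    handler = logging.FileHandler(tmp / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("enosekit")
    root.addHandler(handler)
    try:
        syn_cfg = replace(config.synthetic, seed=derive_seed(config.seed, "simulate"))
        logger.info("simulate: %d grades x %d replicates, hash %s",
                    syn_cfg.n_grades, syn_cfg.replicates_per_grade, syn_cfg.config_hash())
        sample_set = generate_dataset(syn_cfg)
        write_traces(sample_set, tmp / "traces.csv")

        logger.info("repeatability: grade %d", config.chemometrics.rsd_grade)
        rsd = compute_rsd(sample_set, config.chemometrics.rsd_grade, t0=config.features.t0)
        dump_json({"grade": rsd.grade, "t0": rsd.t0, "rsd_percent": rsd.rsd,
                   "max_rsd_percent": rsd.max()}, tmp / "rsd.json")

        logger.info("features: %s", ",".join(FEATURE_CODES))
        fm = extract_features(sample_set, cfg=config.features)
        write_feature_matrix(fm, tmp / "features.csv")

        logger.info("pca: %d components", config.chemometrics.pca_components)
        pca = pca_fit(fm, n_components=config.chemometrics.pca_components)
        dump_json(
            {
                "explained_variance_ratio": pca.explained_variance_ratio,
                "first_two_percent": 100.0 * float(pca.all_ratios[:2].sum()),
                "loadings": pca.loadings,
                "columns": pca.columns,
            },
            tmp / "pca.json",
        )

        logger.info("lda: protocol %s", config.chemometrics.lda_protocol)
        lda = lda_fit(fm, protocol=config.chemometrics.lda_protocol)
        dump_json(
            {
                "protocol": lda.protocol,
                "n_functions": lda.n_functions,
                "accuracy": lda.accuracy,
                "confusion_matrix": lda.confusion_matrix,
                "classes": lda.classes,
                "discriminant_functions": lda.discriminant_functions,
            },
            tmp / "lda.json",
        )

        spec = SplitSpec(
            train_per_class=config.classification.train_per_class,
            seed=derive_seed(config.seed, "benchmark"),
        )
        logger.info("benchmark: %d per class, %d algorithms",
                    spec.train_per_class, len(config.classification.algorithms))
        report = run_benchmark(
            sample_set,
            spec,
            codes=config.classification.codes,
            algorithms=config.classification.algorithms,
            feature_cfg=config.features,
        )
        report.to_json(tmp / "benchmark.json")

        (tmp / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        logger.info("run complete; %d artifacts", len(ARTIFACTS))
    except Exception:
        root.removeHandler(handler)
        handler.close()
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    else:
        root.removeHandler(handler)
        handler.close()
    if outdir.exists():
        shutil.rmtree(outdir)
    tmp.rename(outdir)
    return outdir
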