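"""Synthetic functional-connectome cohorts.

Real disease cohorts of this kind consist of one square correlation matrix per
subject (pairwise functional connectivity between atlas regions, e.g. 90
regions) plus a small phenotype table: age, sex, APOE4 allele count and a
diagnostic label such as AD / MCI / NC.  The generator here reproduces the
statistical structure the downstream classifier relies on:

* a subset of connectivity entries ("signal edges") whose mean shifts with the
  class label,
* strongly imbalanced class counts (default 30 / 92 / 243),
* demographics partially associated with the class (older age, more APOE4
  copies in the severer classes), with the association strength a single dial.

It deliberately does not model BOLD time series, positive-definiteness of the
correlation matrices, or realistic network topology: the classifier consumes
the flattened upper triangle entrywise, so only entrywise statistics matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("subject_id", "age", "sex", "apoe4", "label")
#: non-image features used for population-graph edges, in canonical order
NONIMAGE_FEATURES = ("age", "sex", "apoe4")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_regions : int
        Atlas size; the connectivity vector has d = n_regions*(n_regions-1)/2
        entries. Default 90 (AAL-style parcellation).
    class_counts : sequence of int
        Subjects per class, severest class first. Default (30, 92, 243),
        i.e. AD / MCI / NC scale imbalance.
    n_signal_edges : int
        Number of connectivity entries carrying a class-dependent mean shift.
    effect_size : float
        Mean shift per class step on signal edges, in correlation units;
        class c (0-based) is shifted by ``c * effect_size`` before noise.
    noise_sd : float
        Per-entry Gaussian noise standard deviation.
    demo_assoc : float in [0, 1]
        Strength of the class <-> demographics association. 0 makes age, sex
        and APOE4 independent of the label.
    seed : int
        Seed of the single generator used for everything in one call.
    class_labels : sequence of str, optional
        Class names; defaults to AD/MCI/NC for three classes, else "class0"...
    """

    n_regions: int = 90
    class_counts: tuple[int, ...] = (30, 92, 243)
    n_signal_edges: int = 300
    effect_size: float = 0.2
    noise_sd: float = 0.1
    demo_assoc: float = 0.8
    seed: int = 0
    class_labels: tuple[str, ...] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)

    @property
    def dim(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError(f"n_regions must be >= 2, got {self.n_regions}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if any(int(c) <= 0 for c in self.class_counts):
            raise ValueError(f"class_counts must be positive, got {self.class_counts}")
        if not 0 < self.n_signal_edges <= self.dim:
            raise ValueError(
                f"n_signal_edges must be in [1, {self.dim}], got {self.n_signal_edges}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 <= self.demo_assoc <= 1:
            raise ValueError(f"demo_assoc must be in [0, 1], got {self.demo_assoc}")
        if self.class_labels is not None and len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels length must match class_counts")

    def resolved_labels(self) -> tuple[str, ...]:
        if self.class_labels is not None:
            return tuple(self.class_labels)
        if self.n_classes == 3:
            return ("AD", "MCI", "NC")
        return tuple(f"class{c}" for c in range(self.n_classes))


@dataclass
class SubjectRecord:
    """One subject: flattened upper-triangle connectivity + phenotypes.

    ``label`` is a 0-based class index, or None for prediction-time subjects.
    """

    subject_id: str
    x: np.ndarray  # shape (d,), entries in [-1, 1]
    age: float
    sex: int  # 0 / 1
    apoe4: int  # 0, 1 or 2
    label: int | None

    def nonimage(self) -> np.ndarray:
        return np.array([self.age, self.sex, self.apoe4], dtype=float)


@dataclass
class Cohort:
    """Ordered collection of subjects sharing one atlas."""

    subjects: list[SubjectRecord]
    n_regions: int
    class_labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def dim(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    def feature_matrix(self) -> np.ndarray:
        return np.stack([s.x for s in self.subjects])

    def labels(self) -> np.ndarray:
        """Labels as int array; missing labels become -1."""
        return np.array(
            [-1 if s.label is None else s.label for s in self.subjects], dtype=int
        )

    def phenotypes(self) -> np.ndarray:
        """(N, 3) array of the non-image features age, sex, apoe4."""
        return np.stack([s.nonimage() for s in self.subjects])

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids are not unique")
        d = self.dim
        for s in self.subjects:
            if s.x.shape != (d,):
                raise ValueError(
                    f"subject {s.subject_id}: feature length {s.x.shape[0]} != {d}"
                )
            if np.any(np.abs(s.x) > 1 + 1e-12):
                raise ValueError(
                    f"subject {s.subject_id}: connectivity outside [-1, 1]"
                )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a synthetic cohort.

    Entry (i, c) of the connectivity vector of a class-c subject is

        clip( mu_j + c * effect_size * 1[j in signal] + eps,  -1, 1 ),

    with per-edge population means mu_j ~ N(0.1, 0.15) (drawn once per cohort)
    and eps ~ N(0, noise_sd).  Demographics are drawn per class:

        age   ~ N(66 + 16 * demo_assoc * severity_c, 5)      (years)
        sex   ~ Bernoulli(0.4 + 0.2 * demo_assoc * severity_c)
        apoe4 ~ Binomial(2, 0.05 + 0.65 * demo_assoc * severity_c)

    where severity_c = 1 - c/(C-1) decreases from 1 (class 0, severest) to 0.
    The same seed reproduces the cohort bit for bit.
    """
    config.validate()
    max_shift = (config.n_classes - 1) * config.effect_size
    if max_shift > 2.0:
        logger.warning(
            "largest class mean shift %.3g exceeds the [-1, 1] correlation range; "
            "signal edges will saturate at the clip boundary",
            max_shift,
        )
    rng = np.random.default_rng(config.seed)
    d = config.dim
    C = config.n_classes
    edge_means = rng.normal(0.1, 0.15, size=d)
    signal_edges = rng.choice(d, size=config.n_signal_edges, replace=False)

    subjects: list[SubjectRecord] = []
    total = sum(config.class_counts)
    width = max(4, len(str(total)))
    sid = 0
    for c, count in enumerate(config.class_counts):
        severity = 1.0 - c / (C - 1)
        shift = np.zeros(d)
        shift[signal_edges] = c * config.effect_size
        for _ in range(int(count)):
            x = edge_means + shift + rng.normal(0.0, config.noise_sd, size=d)
            np.clip(x, -1.0, 1.0, out=x)
            age = rng.normal(66.0 + 16.0 * config.demo_assoc * severity, 5.0)
            sex = int(rng.random() < 0.4 + 0.2 * config.demo_assoc * severity)
            apoe4 = int(
                rng.binomial(2, 0.05 + 0.65 * config.demo_assoc * severity)
            )
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{sid:0{width}d}",
                    x=x,
                    age=float(age),
                    sex=sex,
                    apoe4=apoe4,
                    label=c,
                )
            )
            sid += 1
    cohort = Cohort(
        subjects=subjects,
        n_regions=config.n_regions,
        class_labels=config.resolved_labels(),
    )
    cohort.validate()
    return cohort


def signal_edge_indices(config: CohortConfig) -> np.ndarray:
    """Indices of the planted signal edges for a given config (for tests/plots)."""
    rng = np.random.default_rng(config.seed)
    rng.normal(0.1, 0.15, size=config.dim)  # keep stream aligned with generate_cohort
    return rng.choice(config.dim, size=config.n_signal_edges, replace=False)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly through text


def _square_from_vector(x: np.ndarray, n: int) -> np.ndarray:
    M = np.eye(n)
    iu = np.triu_indices(n, k=1)
    M[iu] = x
    M[(iu[1], iu[0])] = x
    return M


def _vector_from_square(M: np.ndarray) -> np.ndarray:
    return M[np.triu_indices(M.shape[0], k=1)]


def write_cohort(cohort: Cohort, path: str | Path, fmt: str = "matrix") -> None:
    """Write a cohort directory.

    ``fmt="matrix"`` writes ``phenotypes.tsv`` plus one whitespace-delimited
    square connectivity matrix per subject (``<subject_id>.txt``);
    ``fmt="wide"`` writes the phenotype table plus a single ``features.tsv``
    of flattened vectors.  Both dialects are read back losslessly.
    """
    if fmt not in ("matrix", "wide"):
        raise ValueError(f"unknown cohort format {fmt!r}")
    cohort.validate()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "phenotypes.tsv", "w") as fh:
        fh.write("\t".join(PHENOTYPE_COLUMNS) + "\n")
        for s in cohort.subjects:
            label = "" if s.label is None else cohort.class_labels[s.label]
            fh.write(
                f"{s.subject_id}\t{_FLOAT_FMT % s.age}\t{s.sex}\t{s.apoe4}\t{label}\n"
            )
    meta = out / "cohort.json"
    import json

    meta.write_text(
        json.dumps(
            {
                "n_regions": cohort.n_regions,
                "class_labels": list(cohort.class_labels),
                "format": fmt,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    if fmt == "matrix":
        for s in cohort.subjects:
            M = _square_from_vector(s.x, cohort.n_regions)
            np.savetxt(out / f"{s.subject_id}.txt", M, fmt=_FLOAT_FMT)
    else:
        d = cohort.dim
        with open(out / "features.tsv", "w") as fh:
            fh.write("subject_id\t" + "\t".join(f"f{j}" for j in range(d)) + "\n")
            for s in cohort.subjects:
                fh.write(
                    s.subject_id + "\t" + "\t".join(_FLOAT_FMT % v for v in s.x) + "\n"
                )


def _parse_phenotypes(path: Path, class_labels: list[str]) -> list[dict]:
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = list(PHENOTYPE_COLUMNS)
        if header[: len(expected) - 1] != expected[:-1]:
            raise ValueError(
                f"{path}: header line must start with {expected[:-1]}, got {header}"
            )
        has_label = len(header) >= 5 and header[4] == "label"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                row = {
                    "subject_id": parts[0],
                    "age": float(parts[1]),
                    "sex": int(parts[2]),
                    "apoe4": int(parts[3]),
                }
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            label: int | None = None
            if has_label and len(parts) >= 5 and parts[4] not in ("", "NA"):
                name = parts[4]
                if name not in class_labels:
                    raise ValueError(
                        f"{path}:{lineno}: unknown class label {name!r}"
                    )
                label = class_labels.index(name)
            row["label"] = label
            rows.append(row)
    return rows


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort` (either dialect)."""
    import json

    root = Path(path)
    meta_path = root / "cohort.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{root}: no cohort.json metadata file")
    meta = json.loads(meta_path.read_text())
    n_regions = int(meta["n_regions"])
    class_labels = list(meta["class_labels"])
    d = n_regions * (n_regions - 1) // 2
    rows = _parse_phenotypes(root / "phenotypes.tsv", class_labels)

    subjects: list[SubjectRecord] = []
    if meta.get("format", "matrix") == "wide":
        feats: dict[str, np.ndarray] = {}
        fpath = root / "features.tsv"
        with open(fpath) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) - 1 != d:
                raise ValueError(
                    f"{fpath}: {len(header) - 1} feature columns, expected {d}"
                )
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != d + 1:
                    raise ValueError(
                        f"{fpath}:{lineno}: {len(parts) - 1} values, expected {d}"
                    )
                x = np.array([float(v) for v in parts[1:]])
                _check_range(x, f"{fpath}:{lineno}")
                feats[parts[0]] = x
        for row in rows:
            if row["subject_id"] not in feats:
                raise ValueError(f"no feature row for subject {row['subject_id']}")
            subjects.append(SubjectRecord(x=feats[row["subject_id"]], **row))
    else:
        for row in rows:
            mpath = root / f"{row['subject_id']}.txt"
            if not mpath.exists():
                raise FileNotFoundError(f"missing connectivity file {mpath}")
            M = np.loadtxt(mpath)
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{mpath}: connectivity matrix is not square")
            if M.shape[0] != n_regions:
                raise ValueError(
                    f"{mpath}: matrix is {M.shape[0]}x{M.shape[0]}, expected {n_regions}"
                )
            x = _vector_from_square(M)
            _check_range(x, str(mpath))
            subjects.append(SubjectRecord(x=x, **row))
    cohort = Cohort(subjects=subjects, n_regions=n_regions, class_labels=tuple(class_labels))
    cohort.validate()
    return cohort


def _check_range(x: np.ndarray, where: str) -> None:
    bad = np.flatnonzero(np.abs(x) > 1 + 1e-12)
    if bad.size:
        raise ValueError(
            f"{where}: connectivity value {x[bad[0]]:.6g} at entry {bad[0]} "
            "is outside [-1, 1]"
        )
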