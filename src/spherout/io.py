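"""Reading and writing angle tables and detection reports.

An angle table is a :class:`pandas.DataFrame` with columns ``id``, ``theta``
(colatitude, radians) and ``phi`` (longitude, radians).  The packaged eye
dataset — anterior-segment optical-coherence-tomography measurements of the
posterior corneal curvature angle (phi) and the eye angle (theta) for 23
patients — ships as a CSV resource and is the worked example used throughout
the documentation and tests.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .sphere import to_cartesian, wrap_longitude

__all__ = ["read_sample", "load_eye_data", "angles_from_table", "write_report", "read_report"]

# coordinates the modified worked example moves patient 10 to, adjacent to
# patient 17, so that the data contain a patch of two outliers
MODIFIED_OBS10 = {"theta": 0.9599, "phi": 0.6109}

_COL_ORDERS = ("theta-phi", "phi-theta")


def _validate_table(df: pd.DataFrame, on_invalid: str = "raise") -> pd.DataFrame:
    theta = df["theta"].to_numpy(dtype=float)
    phi = df["phi"].to_numpy(dtype=float)
    if not (np.isfinite(theta).all() and np.isfinite(phi).all()):
        bad = df.index[~(np.isfinite(theta) & np.isfinite(phi))].tolist()
        raise ValueError(f"non-finite angles in rows {bad}")
    out_of_range = (theta < 0.0) | (theta > np.pi)
    if out_of_range.any():
        if on_invalid == "raise":
            bad = df.index[out_of_range].tolist()
            raise ValueError(
                f"colatitude outside [0, pi] in rows {bad}; "
                "pass on_invalid='wrap' to fold them back"
            )
        # wrap: reflect theta into [0, pi] via the sphere's double cover,
        # shifting phi by pi where the reflection crosses a pole
        theta = np.mod(theta, 2.0 * np.pi)
        over = theta > np.pi
        theta = np.where(over, 2.0 * np.pi - theta, theta)
        phi = np.where(over, phi + np.pi, phi)
    df = df.copy()
    df["theta"] = theta
    df["phi"] = wrap_longitude(phi)
    return df


def read_sample(
    path,
    col_order: str = "phi-theta",
    delimiter: str = ",",
    degrees: bool = False,
    on_invalid: str = "raise",
) -> pd.DataFrame:
    """Read a delimited angle file into an angle table.

    The file needs a header.  Columns named ``theta``/``phi`` are used
    directly; otherwise the first non-id column pair is interpreted per
    ``col_order`` (default ``"phi-theta"``, the layout of the eye-data
    table).  A column named ``id`` or ``patient``, or the first column when
    three columns are present, provides observation labels; labels default
    to 1..n.
    """
    if col_order not in _COL_ORDERS:
        raise ValueError(f"col_order must be one of {_COL_ORDERS}")
    try:
        raw = pd.read_csv(path, delimiter=delimiter, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if raw.empty:
        raise ValueError(f"{path}: no data rows")
    cols = {c.strip().lower(): c for c in raw.columns}

    id_col = next((cols[c] for c in ("id", "patient", "obs") if c in cols), None)
    if "theta" in cols and "phi" in cols:
        theta, phi = raw[cols["theta"]], raw[cols["phi"]]
    else:
        angle_cols = [c for c in raw.columns if c != id_col]
        if id_col is None and len(angle_cols) > 2:
            id_col, angle_cols = angle_cols[0], angle_cols[1:]
        if len(angle_cols) < 2:
            raise ValueError(f"{path}: need two angle columns, found {list(raw.columns)}")
        first, second = raw[angle_cols[0]], raw[angle_cols[1]]
        theta, phi = (first, second) if col_order == "theta-phi" else (second, first)

    def _numeric(s, name):
        vals = pd.to_numeric(s, errors="coerce")
        if vals.isna().any():
            bad = (vals.index[vals.isna()] + 2).tolist()  # header is line 1
            raise ValueError(f"{path}: non-numeric {name} values at line(s) {bad}")
        return vals.to_numpy(dtype=float)

    theta = _numeric(theta, "theta")
    phi = _numeric(phi, "phi")
    if degrees:
        theta, phi = np.deg2rad(theta), np.deg2rad(phi)
    ids = raw[id_col] if id_col is not None else pd.RangeIndex(1, len(raw) + 1)
    df = pd.DataFrame({"id": np.asarray(ids), "theta": theta, "phi": phi})
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate observation ids")
    return _validate_table(df, on_invalid=on_invalid)


def load_eye_data(modified: bool = False) -> pd.DataFrame:
    """The 23-patient eye dataset as an angle table.

    With ``modified=True``, patient 10 is relocated to (theta=0.9599,
    phi=0.6109) next to patient 17, creating a patch of two outliers.
    """
    with resources.files("spherout.data").joinpath("eye_data.csv").open() as fh:
        df = read_sample(fh)
    if modified:
        df.loc[df["id"] == 10, ["theta", "phi"]] = (
            MODIFIED_OBS10["theta"],
            MODIFIED_OBS10["phi"],
        )
    return df


def angles_from_table(df: pd.DataFrame) -> np.ndarray:
    """Direction cosines ``(n, 3)`` of an angle table."""
    return to_cartesian(df["theta"].to_numpy(), df["phi"].to_numpy())


def write_report(result, path, table: pd.DataFrame | None = None, *,
                 kappa=None, mean_direction=None, seed=None, precision: int = 4) -> None:
    """Write a detection result as a commented CSV report.

    A ``#``-prefixed summary header (statistic, cut-off, flagged ids, kappa,
    mean direction, seed) precedes one row per observation with its
    statistic value and flag; the file re-reads with
    ``pandas.read_csv(..., comment='#')``.
    """
    n = len(result.per_obs)
    ids = table["id"].to_numpy() if table is not None else np.arange(1, n + 1)
    flagged_ids = [ids[i] for i in result.flagged]
    fmt = f"%.{precision}f"
    lines = [
        f"# statistic: {result.statistic}" + (f"^{result.k_used}" if result.k_used else ""),
        f"# level: {result.level}",
        f"# cutoff: {fmt % result.cutoff}",
        f"# flagged: {', '.join(str(i) for i in flagged_ids) if flagged_ids else 'no outliers detected'}",
    ]
    if result.stopped_at_k is not None:
        lines.append(f"# stopped_at_k: {result.stopped_at_k}")
    if result.declared_patch_size is not None:
        lines.append(f"# declared_patch_size: {result.declared_patch_size}")
    if kappa is None:
        kappa = getattr(result, "kappa", None)
    if kappa is not None:
        lines.append(f"# kappa: {fmt % kappa}")
    if mean_direction is not None:
        lines.append(f"# mean_direction_theta_phi: {fmt % mean_direction[0]}, {fmt % mean_direction[1]}")
    if seed is not None:
        lines.append(f"# seed: {seed}")

    body = pd.DataFrame({"id": ids})
    if table is not None:
        body["theta"] = table["theta"].to_numpy()
        body["phi"] = table["phi"].to_numpy()
    for k, vals in (result.all_values or {result.k_used: result.per_obs}).items():
        col = f"Q{k}" if result.statistic == "Q" else result.statistic
        body[col] = np.round(vals, precision)
    body["flagged"] = [i in result.flagged for i in range(n)]

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        body.to_csv(fh, index=False, float_format=fmt)


def read_report(path) -> pd.DataFrame:
    """Read back the per-observation block of a report written by :func:`write_report`."""
    return pd.read_csv(path, comment="#")
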