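"""Delimited-text serialization for sessions, parameters, and configs.

Sessions are stored as tab-separated text with a schema-version header
line, one row per trial.  Formatting is canonical (money and ratings to
6 decimal places) so that ``write(read(path)) == path`` byte-for-byte for
canonical files, which keeps pipeline outputs diffable and reproducible.

Schema (v1)::

    # moodrpe-session v1 variant=<variant> endowment=<points|NA>
    index  choice  certain  gamble_hi  gamble_lo  gamble_p  outcome  revealed  rpe  probe  rating

``certain``/``gamble_*`` describe the offered options; ``outcome`` is the
realised amount (NA when hidden); ``rpe`` is stored explicitly so the
zeroing conventions are checkable on file content; probe rows carry the
happiness rating in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .model import MoodParams
from .task import Gamble, MalformedTrialError, Session, TrialRecord, gamble_ev

__all__ = [
    "read_session",
    "write_session",
    "read_params",
    "write_params",
    "read_config",
    "write_config",
    "write_manifest",
    "SessionSchemaError",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

_COLUMNS = (
    "index", "choice", "certain", "gamble_hi", "gamble_lo", "gamble_p",
    "outcome", "revealed", "rpe", "probe", "rating",
)

_NA = "NA"


class SessionSchemaError(ValueError):
    """A session file violates the schema or a task invariant."""


def _fmt(v: float | None) -> str:
    return _NA if v is None else f"{v:.6f}"


def write_session(session: Session, path) -> None:
    """Write a session in the canonical v1 tab-separated format."""
    path = Path(path)
    probe_set = {int(t): i for i, t in enumerate(session.probe_after)}
    lines = [
        f"# moodrpe-session v{SCHEMA_VERSION} variant={session.variant} "
        f"endowment={_fmt(session.endowment)}",
        "\t".join(_COLUMNS),
    ]
    for tr in session.trials:
        g = tr.offered_gamble
        probe_i = probe_set.get(tr.index)
        rating = None
        if probe_i is not None and session.ratings is not None:
            rating = float(session.ratings[probe_i])
        lines.append(
            "\t".join(
                [
                    str(tr.index),
                    tr.choice,
                    _fmt(tr.offered_certain),
                    _fmt(None if g is None else g.outcome_hi),
                    _fmt(None if g is None else g.outcome_lo),
                    _fmt(None if g is None else g.p_hi),
                    _fmt(tr.outcome),
                    str(int(tr.revealed)),
                    _fmt(tr.rpe),
                    str(int(probe_i is not None)),
                    _fmt(rating),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _parse_float(s: str, row: int, col: str) -> float | None:
    if s == _NA:
        return None
    try:
        return float(s)
    except ValueError:
        raise SessionSchemaError(f"row {row}, column {col!r}: not a number: {s!r}")


def read_session(path, strict: bool = True) -> Session:
    """Read and validate a v1 session file.

    Validation enforces the task invariants on file content: probe gaps in
    {2, 3}, zero RPE whenever the outcome was not revealed, chosen-option
    term consistency, and (``strict``) the variant's printed trial/probe
    counts.  Errors name the offending row and column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# moodrpe-session"):
        raise SessionSchemaError(f"{path}: missing session header line")
    header = dict(
        kv.split("=", 1) for kv in lines[0].split()[3:] if "=" in kv
    )
    head_fields = lines[0].split()
    if len(head_fields) < 3 or head_fields[2] != f"v{SCHEMA_VERSION}":
        raise SessionSchemaError(f"{path}: unsupported schema version")
    variant = header.get("variant")
    endowment = _parse_float(header.get("endowment", _NA), 0, "endowment")
    if lines[1].split("\t") != list(_COLUMNS):
        raise SessionSchemaError(f"{path}: column header mismatch")

    trials: list[TrialRecord] = []
    probe_after: list[int] = []
    ratings: list[float] = []
    any_rating = False
    for row, line in enumerate(lines[2:], start=1):
        vals = line.split("\t")
        if len(vals) != len(_COLUMNS):
            raise SessionSchemaError(
                f"row {row}: expected {len(_COLUMNS)} columns, got {len(vals)}"
            )
        rec = dict(zip(_COLUMNS, vals))
        idx = int(rec["index"])
        choice = rec["choice"]
        certain = _parse_float(rec["certain"], row, "certain")
        ghi = _parse_float(rec["gamble_hi"], row, "gamble_hi")
        glo = _parse_float(rec["gamble_lo"], row, "gamble_lo")
        gp = _parse_float(rec["gamble_p"], row, "gamble_p")
        outcome = _parse_float(rec["outcome"], row, "outcome")
        revealed = bool(int(rec["revealed"]))
        rpe = _parse_float(rec["rpe"], row, "rpe") or 0.0
        probe = bool(int(rec["probe"]))
        rating = _parse_float(rec["rating"], row, "rating")

        gamble = None
        if ghi is not None:
            if glo is None or gp is None:
                raise SessionSchemaError(
                    f"row {row}: incomplete gamble specification"
                )
            gamble = Gamble(ghi, glo, gp)
        if not revealed and rpe != 0.0:
            raise SessionSchemaError(
                f"row {row}, column 'rpe': RPE must be zero when the outcome "
                "is not revealed"
            )
        cr = certain if choice == "certain" else 0.0
        # EV of the chosen option: recoverable as outcome − RPE when the
        # outcome was shown, else from the offered gamble (risky variants
        # always resolve the offered gamble).
        if choice in ("gamble", "observation", "other") and gamble is not None:
            if revealed and outcome is not None:
                ev = outcome - rpe
            else:
                ev = gamble_ev(gamble)
        else:
            ev = 0.0
        tr = TrialRecord(
            index=idx,
            choice=choice,
            cr=cr or 0.0,
            ev=ev,
            outcome=outcome,
            revealed=revealed,
            rpe=rpe,
            offered_certain=certain,
            offered_gamble=gamble,
        )
        try:
            tr.validate()
        except MalformedTrialError as e:
            raise SessionSchemaError(f"row {row}: {e}") from e
        trials.append(tr)
        if probe:
            probe_after.append(idx)
            ratings.append(np.nan if rating is None else rating)
            if rating is not None:
                any_rating = True

    session = Session(
        variant=variant,
        trials=trials,
        probe_after=probe_after,
        endowment=endowment,
        ratings=np.asarray(ratings) if any_rating else None,
    )
    try:
        session.validate(strict=strict)
    except (ValueError, MalformedTrialError) as e:
        raise SessionSchemaError(f"{path}: {e}") from e
    return session


# ---------------------------------------------------------------------------
# parameter and config files

def write_params(params: MoodParams, path) -> None:
    """Key-value text round-tripping a parameter vector exactly (repr
    precision)."""
    lines = []
    for k, v in asdict(params).items():
        if v is not None:
            lines.append(f"{k} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> MoodParams:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        kv[k.strip()] = float(v.strip())
    return MoodParams(**kv)


def write_config(config_dict: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_dict, sort_keys=True))


def read_config(path) -> dict:
    out = yaml.safe_load(Path(path).read_text())
    if not isinstance(out, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return out


# ---------------------------------------------------------------------------
# run manifests

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, config_dict: dict, seeds: dict, files: list) -> Path:
    """Record config snapshot, seeds, package version, and per-file digests."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "package": "moodrpe",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": config_dict,
        "seeds": seeds,
        "files": {
            str(Path(f).relative_to(out_dir)): _sha256(Path(f)) for f in files
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
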