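"""Shared plumbing for the numbered analysis drivers."""

import argparse
import hashlib
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"


def make_parser(description: str) -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=None,
                    help="overrides the config seed")
    ap.add_argument("--config", type=str, default=None,
                    help="YAML pipeline config (defaults used otherwise)")
    ap.add_argument("--out", type=str, default=str(RESULTS),
                    help="output directory")
    return ap


def load_cfg(args):
    from relieflearn.config import PipelineConfig, load_config
    cfg = load_config(args.config) if args.config else PipelineConfig()
    if args.seed is not None:
        cfg.seed = args.seed
    return cfg


def write_manifest(out_dir: Path, name: str, cfg, extra=None):
    import relieflearn
    payload = {"script": name, "config": cfg.to_dict(),
               "package_version": relieflearn.__version__,
               "python": sys.version.split()[0]}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload["config"], sort_keys=True).encode()).hexdigest()[:16]
    if extra:
        payload.update(extra)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{name}_manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2)
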