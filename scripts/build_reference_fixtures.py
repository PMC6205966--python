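"""Regenerate the shipped synthetic reference fixtures under
src/panscan/data/ from the deterministic builders in panscan.references.

Run from the repository root:  python scripts/build_reference_fixtures.py
"""

from pathlib import Path

from panscan.references import dump_fixtures

OUT = Path(__file__).resolve().parent.parent / "src" / "panscan" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for fname, text in dump_fixtures().items():
        (OUT / fname).write_text(text)
        print(f"wrote {OUT / fname} ({len(text)} bytes)")


if __name__ == "__main__":
    main()
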