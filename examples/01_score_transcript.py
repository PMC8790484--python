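"""Score a five-word fluency transcript and classify its errors.

The sequence "tiger, car, elephant, lion, tiger" contains one intrusion
("car" is not an animal) and one perseveration (the repeated "tiger").
"""

import numpy as np

from vflda import Lexicon, Transcript, score_transcript

lexicon = Lexicon(frozenset({"tiger", "elephant", "lion", "cow", "horse"}))
transcript = Transcript("demo", "ad", [
    ("tiger", 2.0), ("car", 6.5), ("elephant", 11.0),
    ("lion", 15.5), ("tiger", 21.0)])

# "car" is a real word outside the category; give it a topic profile so it
# is scored as an intrusion rather than a non-word utterance
car = np.zeros(14)
car[7] = 1.0
scored = score_transcript(transcript, lexicon, {"car": car})

for r in scored:
    print(f"{r.onset:5.1f}s  {r.word:<10s} {r.label}")
print("\nintrusions:", sum(r.label == "intrusion" for r in scored),
      "| perseverations:", sum(r.label == "perseveration" for r in scored))
# Each response gets exactly one label; a repeat of ANY earlier word is a
# perseveration, and the first out-of-category production is an intrusion.
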