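{
  "_comment": "Synthetic stand-in MET table assembled from 2011 Adult Compendium conventions; the study's own per-code values were not published. Supply your own table for real analyses.",
  "101": 2.3,
  "102": 3.0,
  "103": 7.5,
  "104": 7.3,
  "105": 5.5,
  "106": 7.0,
  "107": 3.0,
  "108": 7.3,
  "109": 7.0,
  "110": 3.8,
  "111": 3.3,
  "112": 5.5,
  "113": 4.5,
  "114": 11.0,
  "115": 7.0,
  "116": 5.0,
  "201": 1.0,
  "202": 1.3,
  "203": 1.5,
  "204": 1.8,
  "205": 3.5,
  "206": 2.0,
  "207": 1.5,
  "208": 1.5,
  "209": 2.5,
  "210": 2.5,
  "211": 2.0,
  "301": 1.8,
  "302": 1.5,
  "303": 2.0,
  "304": 2.0,
  "305": 3.5,
  "306": 2.5,
  "307": 4.5
}
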