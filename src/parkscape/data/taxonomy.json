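{
  "101": {"name": "stretching", "category": "EB"},
  "102": {"name": "tai chi", "category": "EB"},
  "103": {"name": "bicycling", "category": "EB"},
  "104": {"name": "aerobic dance", "category": "EB"},
  "105": {"name": "badminton", "category": "EB"},
  "106": {"name": "running", "category": "EB"},
  "107": {"name": "frisbee playing", "category": "EB"},
  "108": {"name": "tennis", "category": "EB"},
  "109": {"name": "kickball", "category": "EB"},
  "110": {"name": "calisthenics", "category": "EB"},
  "111": {"name": "tai chi chuan", "category": "EB"},
  "112": {"name": "social dancing", "category": "EB"},
  "113": {"name": "kicking shuttlecock", "category": "EB"},
  "114": {"name": "rope jumping", "category": "EB"},
  "115": {"name": "skating", "category": "EB"},
  "116": {"name": "scooter riding", "category": "EB"},
  "201": {"name": "sleeping", "category": "LB"},
  "202": {"name": "sitting", "category": "LB"},
  "203": {"name": "standing", "category": "LB"},
  "204": {"name": "drawing", "category": "LB"},
  "205": {"name": "walking", "category": "LB"},
  "206": {"name": "photography", "category": "LB"},
  "207": {"name": "chess game", "category": "LB"},
  "208": {"name": "card game", "category": "LB"},
  "209": {"name": "feeding animals", "category": "LB"},
  "210": {"name": "bird watching", "category": "LB"},
  "211": {"name": "playing with sand", "category": "LB"},
  "301": {"name": "reunion activities", "category": "SB"},
  "302": {"name": "group conversation", "category": "SB"},
  "303": {"name": "playing musical instruments", "category": "SB"},
  "304": {"name": "singing", "category": "SB"},
  "305": {"name": "parent-child activities", "category": "SB"},
  "306": {"name": "camping", "category": "SB"},
  "307": {"name": "children's games", "category": "SB"}
}
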