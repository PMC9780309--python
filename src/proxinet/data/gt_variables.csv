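table,column,description
GT1,pair,dyad identifier of the two observed participants
GT1,t,scan timestamp in seconds since the project reference midnight (10-s scan sampling)
GT1,interaction,1 if the dyad was in face-to-face interaction at the scan, 0 otherwise
GT1,orientation,relative body orientation code (FF face-to-face, SS side-by-side, BB back-to-back)
GT2,pair,dyad identifier of the two statically positioned participants
GT2,t,timestamp in seconds since the project reference midnight
GT2,distance_cm,experimentally fixed distance between the badges in centimetres
GT2,orientation,relative orientation code (FF, SS, BB)
GT2,rssi,received signal strength recorded at the fixed setting (dBm)
GT3,session,observation session identifier
GT3,t,scan timestamp in seconds since the project reference midnight (2-min scan sampling)
GT3,id_a,first participant of the scanned pair
GT3,id_b,second participant of the scanned pair
GT3,distance_m,observed distance between the two participants in metres
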