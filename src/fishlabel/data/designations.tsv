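commercial_name	pattern_type	patterns
tuna	genus	Thunnus
yellowfin tuna	species	Thunnus albacares
bluefin tuna	species	Thunnus thynnus;Thunnus orientalis;Thunnus maccoyii
albacore	species	Thunnus alalunga
eel	genus	Anguilla
seabass	species	Dicentrarchus labrax
yellowtail	genus	Seriola
kingfish	genus	Scomberomorus
swordfish	species	Xiphias gladius
snapper	family	Lutjanidae
flying fish	family	Exocoetidae
mackerel	genus	Scomber
seabream	species	Sparus aurata
sablefish	species	Anoplopoma fimbria
barramundi	species	Lates calcarifer
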